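"""Deterministic bench calculators: transfection recipes and Ct-based expression.

The recipe calculator covers both delivery formats: the well format, where the
payload is diluted into the volume added to each well, and the array format,
where the "final" volume is the pooled printing mix itself (the in-cell dose
after reverse transfection is not a computable quantity).

Relative mRNA quantification uses the standard fold-change scheme
``efficiency ** (-ddCt)`` with the target gene normalised to a reference gene
and a calibrator sample (default efficiency 2.0, i.e. perfect doubling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RecipeComponent",
    "TransfectionRecipe",
    "CtTable",
    "final_payload_concentration",
    "relative_expression",
    "well_recipe",
    "array_recipe",
]


@dataclass
class RecipeComponent:
    name: str
    volume_ul: float
    stock_concentration_um: float | None = None  # micromolar; None for carriers
    is_payload: bool = False

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError(f"component {self.name!r}: volume must be positive")


@dataclass
class TransfectionRecipe:
    """A transfection mix: components plus the final delivered volume.

    ``format`` is "well" (volume added per well) or "array" (pooled print mix).
    If ``final_delivery_volume_ul`` is None it defaults to the sum of component
    volumes (the natural choice for the array format).
    """

    components: list[RecipeComponent]
    format: str = "well"
    final_delivery_volume_ul: float | None = None

    def __post_init__(self) -> None:
        if self.format not in ("well", "array"):
            raise ValueError("format must be 'well' or 'array'")
        n_payload = sum(c.is_payload for c in self.components)
        if n_payload > 1:
            raise ValueError("at most one component may be flagged as the payload")

    @property
    def total_component_volume_ul(self) -> float:
        return sum(c.volume_ul for c in self.components)

    @property
    def final_volume_ul(self) -> float:
        if self.final_delivery_volume_ul is not None:
            return self.final_delivery_volume_ul
        return self.total_component_volume_ul

    def payload(self) -> RecipeComponent:
        for c in self.components:
            if c.is_payload:
                return c
        raise ValueError("recipe has no payload component")

    def to_csv(self, path) -> None:
        """Header: name,volume_ul,stock_concentration_um,is_payload (one row per component)."""
        pd.DataFrame(
            {
                "name": [c.name for c in self.components],
                "volume_ul": [c.volume_ul for c in self.components],
                "stock_concentration_um": [c.stock_concentration_um for c in self.components],
                "is_payload": [c.is_payload for c in self.components],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, format: str = "well", final_delivery_volume_ul: float | None = None):
        df = pd.read_csv(path)
        comps = [
            RecipeComponent(
                name=str(r.name),
                volume_ul=float(r.volume_ul),
                stock_concentration_um=(
                    None if pd.isna(r.stock_concentration_um) else float(r.stock_concentration_um)
                ),
                is_payload=bool(r.is_payload),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(components=comps, format=format, final_delivery_volume_ul=final_delivery_volume_ul)

    def scaled(self, factor: float) -> "TransfectionRecipe":
        """All volumes multiplied by a positive constant (concentrations unchanged)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        comps = [
            RecipeComponent(c.name, c.volume_ul * factor, c.stock_concentration_um, c.is_payload)
            for c in self.components
        ]
        fv = None if self.final_delivery_volume_ul is None else self.final_delivery_volume_ul * factor
        return TransfectionRecipe(components=comps, format=self.format, final_delivery_volume_ul=fv)


def final_payload_concentration(recipe: TransfectionRecipe) -> float:
    """Concentration of the nucleic-acid payload in the delivered volume, in nM.

    moles = stock (uM) x payload volume (uL); concentration = moles / final
    volume, converted to nanomolar.
    """
    payload = recipe.payload()
    if payload.stock_concentration_um is None:
        raise ValueError("payload component has no stock concentration")
    final_volume = recipe.final_volume_ul
    if final_volume <= 0:
        raise ValueError("final delivery volume must be positive")
    return payload.stock_concentration_um * payload.volume_ul / final_volume * 1000.0


def well_recipe(
    sirna_volume_ul: float = 5.0,
    sirna_stock_um: float = 1.0,
    final_volume_ul: float = 100.0,
) -> TransfectionRecipe:
    """The forward-transfection mix delivered to one 96-well plate well.

    Defaults: 0.1 uL lipofection reagent + 9.9 uL medium, 5 uL of 1 uM siRNA
    + 5 uL medium, then 80 uL complete medium; 100 uL delivered per well.
    """
    return TransfectionRecipe(
        components=[
            RecipeComponent("lipofectamine", 0.1),
            RecipeComponent("DMEM (reagent dilution)", 9.9),
            RecipeComponent("siRNA", sirna_volume_ul, sirna_stock_um, is_payload=True),
            RecipeComponent("DMEM (siRNA dilution)", 5.0),
            RecipeComponent("complete medium", 80.0),
        ],
        format="well",
        final_delivery_volume_ul=final_volume_ul,
    )


def array_recipe(sirna_volume_ul: float = 2.0, sirna_stock_um: float = 20.0) -> TransfectionRecipe:
    """The pooled reverse-transfection printing mix (per library well).

    3 uL lipofection reagent, 2 uL of 20 uM siRNA, 2 uL sucrose/OptiMEM,
    2 uL RNase-free water, 2 uL of 20 uM tracer RNA, 5 uL gelatin: 16 uL pool.
    """
    return TransfectionRecipe(
        components=[
            RecipeComponent("lipofectamine", 3.0),
            RecipeComponent("siRNA", sirna_volume_ul, sirna_stock_um, is_payload=True),
            RecipeComponent("sucrose in OptiMEM", 2.0),
            RecipeComponent("RNase-free water", 2.0),
            RecipeComponent("siGLO tracer", 2.0, 20.0),
            RecipeComponent("gelatin", 5.0),
        ],
        format="array",
    )


@dataclass
class CtTable:
    """Per-sample cycle-threshold values for a target and a reference gene."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    calibrator_sample: str = ""

    REQUIRED = ("sample", "target_ct", "reference_ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        if self.rows["sample"].duplicated().any():
            dupes = self.rows.loc[self.rows["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample names: {dupes}")
        for col in ("target_ct", "reference_ct"):
            vals = self.rows[col]
            if not ((vals > 0).all() and vals.map(pd.notna).all() and (vals < float("inf")).all()):
                raise ValueError(f"{col} values must be finite and positive")
        if self.calibrator_sample not in set(self.rows["sample"]):
            raise ValueError(f"calibrator sample {self.calibrator_sample!r} not present")

    @classmethod
    def from_records(cls, records, calibrator_sample: str) -> "CtTable":
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(rows=df, calibrator_sample=calibrator_sample)

    @classmethod
    def from_csv(cls, path, calibrator_sample: str) -> "CtTable":
        return cls(rows=pd.read_csv(path), calibrator_sample=calibrator_sample)


def relative_expression(ct: CtTable, efficiency: float = 2.0) -> pd.DataFrame:
    """Per-sample fold change relative to the calibrator.

    dCt = target_ct - reference_ct; ddCt = dCt_sample - dCt_calibrator;
    fold = efficiency ** (-ddCt). The calibrator maps to exactly 1.0.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1.0")
    df = ct.rows.copy()
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    cal_dct = float(df.loc[df["sample"] == ct.calibrator_sample, "delta_ct"].iloc[0])
    df["delta_delta_ct"] = df["delta_ct"] - cal_dct
    df["fold_change"] = efficiency ** (-df["delta_delta_ct"])
    df.loc[df["sample"] == ct.calibrator_sample, "fold_change"] = 1.0
    return df[["sample", "delta_ct", "delta_delta_ct", "fold_change"]]
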