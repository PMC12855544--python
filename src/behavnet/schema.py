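"""Variable schema and model-specific encodings.

A :class:`VariableSpec` describes one covariate: its measurement scale
(binary / ordinal / nominal / continuous), its levels and reference level,
and how it is encoded for each of the two analytic frameworks the package
implements:

* **Cox encoding** — dummy/indicator coding with an explicit reference level,
  the convention used for interpretable hazard ratios (continuous variables
  may be binned into epidemiological categories via ``cox_bins``);
* **ANN encoding** — min–max scaled continuous inputs, binary indicators and
  full one-hot blocks, the convention used for the feedforward influence
  networks (multi-level frequency variables may be collapsed to a single
  top-category or ever/never contrast via ``ann_collapse``).

The default schema mirrors the structure of a laboratory-free behavioral
risk model for incident type 2 diabetes: psychosocial and sleep flags,
smoking history, dietary frequency and type variables, and continuous age
and body-mass index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "default_schema",
    "cox_design",
    "cox_term_names",
    "schema_to_json",
    "schema_from_json",
]

_SCALES = {"binary", "ordinal", "nominal", "continuous"}
_COX_ENCODINGS = {"binary_indicator", "ordinal_numeric", "dummy_set"}
_ANN_ENCODINGS = {"binary_indicator", "one_hot", "minmax_continuous"}


@dataclass
class VariableSpec:
    """Measurement scale, levels and per-model encoding rules for one covariate.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    scale : {'binary', 'ordinal', 'nominal', 'continuous'}
    levels : list
        Ordered level labels; empty for continuous variables.
    reference_level : object
        Must be one of ``levels`` for non-continuous scales.
    cox_encoding : {'binary_indicator', 'ordinal_numeric', 'dummy_set'}
    ann_encoding : {'binary_indicator', 'one_hot', 'minmax_continuous'}
    gen_params : dict
        Either ``{'probs': [...]}`` (level probabilities summing to 1) or
        ``{'range': [lo, hi]}`` for continuous variables.
    cox_bins : dict, optional
        For continuous variables that enter the Cox model as categories:
        ``{'edges': [...], 'labels': [...], 'reference': label}``.
    ann_collapse : str, optional
        For multi-level variables entering the ANN as a single indicator:
        ``'top_level'`` (highest level vs all lower) or ``'ever'`` (any
        non-reference level vs reference).
    """

    name: str
    scale: str
    levels: list = field(default_factory=list)
    reference_level: object = None
    cox_encoding: str = "binary_indicator"
    ann_encoding: str = "binary_indicator"
    gen_params: dict = field(default_factory=dict)
    cox_bins: Optional[dict] = None
    ann_collapse: Optional[str] = None

    def __post_init__(self):
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")
        if self.cox_encoding not in _COX_ENCODINGS:
            raise ValueError(f"unknown cox_encoding {self.cox_encoding!r}")
        if self.ann_encoding not in _ANN_ENCODINGS:
            raise ValueError(f"unknown ann_encoding {self.ann_encoding!r}")
        if self.scale == "continuous":
            rng = self.gen_params.get("range")
            if not rng or len(rng) != 2 or not rng[0] < rng[1]:
                raise ValueError(
                    f"continuous variable {self.name} needs gen_params"
                    f"['range'] = [lo, hi] with lo < hi"
                )
        else:
            if not self.levels:
                raise ValueError(f"{self.name}: non-continuous variable needs levels")
            if self.reference_level not in self.levels:
                raise ValueError(
                    f"{self.name}: reference {self.reference_level!r} not in levels"
                )
            probs = self.gen_params.get("probs")
            if probs is not None:
                if len(probs) != len(self.levels):
                    raise ValueError(f"{self.name}: probs/levels length mismatch")
                if abs(sum(probs) - 1.0) > 1e-12:
                    raise ValueError(f"{self.name}: level probabilities must sum to 1")

    # ------------------------------------------------------------------
    @property
    def is_continuous(self) -> bool:
        return self.scale == "continuous"

    def cox_columns(self) -> list:
        """Names of the design columns this variable contributes to the Cox model."""
        if self.cox_encoding == "binary_indicator":
            return [self.name]
        if self.cox_encoding == "ordinal_numeric":
            return [self.name]
        # dummy_set
        if self.is_continuous:
            bins = self.cox_bins
            if bins is None:
                raise ValueError(f"{self.name}: dummy_set on continuous needs cox_bins")
            return [
                f"{self.name}[{lab}]"
                for lab in bins["labels"]
                if lab != bins["reference"]
            ]
        return [
            f"{self.name}[{lev}]" for lev in self.levels if lev != self.reference_level
        ]


def _bin(x: pd.Series, spec: VariableSpec) -> pd.Series:
    bins = spec.cox_bins
    edges = np.asarray(bins["edges"], dtype=float)
    idx = np.clip(np.searchsorted(edges, x.to_numpy(dtype=float), side="right") - 1,
                  0, len(bins["labels"]) - 1)
    return pd.Series(np.asarray(bins["labels"], dtype=object)[idx], index=x.index)


def cox_design(table: pd.DataFrame, schema: list[VariableSpec]) -> pd.DataFrame:
    """Expand a typed cohort table into the Cox design matrix.

    Binary variables become 0/1 indicators, ordinal variables their numeric
    level index, nominal variables a dummy set excluding the reference level,
    and continuous variables with ``cox_bins`` a dummy set over their bins.
    """
    cols = {}
    for spec in schema:
        x = table[spec.name]
        if spec.cox_encoding == "binary_indicator":
            one = spec.levels[-1] if spec.levels else 1
            cols[spec.name] = (x == one).astype(float)
        elif spec.cox_encoding == "ordinal_numeric":
            mapping = {lev: i for i, lev in enumerate(spec.levels)}
            cols[spec.name] = x.map(mapping).astype(float)
        else:  # dummy_set
            cat = _bin(x, spec) if spec.is_continuous else x
            ref = spec.cox_bins["reference"] if spec.is_continuous else spec.reference_level
            labels = spec.cox_bins["labels"] if spec.is_continuous else spec.levels
            for lev in labels:
                if lev == ref:
                    continue
                cols[f"{spec.name}[{lev}]"] = (cat == lev).astype(float)
    return pd.DataFrame(cols, index=table.index)


def numeric_design(table: pd.DataFrame, schema: list[VariableSpec]) -> pd.DataFrame:
    """Fully numeric representation preserving continuous resolution.

    Unlike :func:`cox_design`, continuous variables stay continuous (no
    epidemiological binning): binary -> indicator, ordinal -> numeric level
    index, nominal -> dummy set, continuous -> raw float.  This is the
    representation the unsupervised preprocessing (standardization,
    embedding, outlier flagging) operates on.
    """
    cols = {}
    for spec in schema:
        if spec.name not in table.columns:
            continue
        x = table[spec.name]
        if spec.is_continuous:
            cols[spec.name] = pd.to_numeric(x).astype(float)
        elif spec.cox_encoding == "binary_indicator":
            one = spec.levels[-1] if spec.levels else 1
            cols[spec.name] = (x == one).astype(float)
        elif spec.scale == "ordinal":
            mapping = {lev: i for i, lev in enumerate(spec.levels)}
            cols[spec.name] = x.map(mapping).astype(float)
        else:
            for lev in spec.levels:
                if lev == spec.reference_level:
                    continue
                cols[f"{spec.name}[{lev}]"] = (x == lev).astype(float)
    return pd.DataFrame(cols, index=table.index)


def cox_term_names(schema: list[VariableSpec]) -> list:
    """All Cox design column names, in schema order."""
    out = []
    for spec in schema:
        out.extend(spec.cox_columns())
    return out


# ----------------------------------------------------------------------
# Default schema
# ----------------------------------------------------------------------

def _binary(name, p1, **kw):
    return VariableSpec(
        name=name, scale="binary", levels=[0, 1], reference_level=0,
        cox_encoding="binary_indicator", ann_encoding="binary_indicator",
        gen_params={"probs": [1 - p1, p1]}, **kw,
    )


MEAT_LEVELS = ["never", "lt_once_week", "once_week", "2_4_week", "5_6_week", "daily"]


def default_schema() -> list[VariableSpec]:
    """The default behavioral predictor schema.

    Ten binary psychosocial/sleep/gaming/smoking flags plus binary cheese
    intake, a three-level smoking history, four-level ordinal added salt,
    nominal bread (reference wholewheat) and cereal (reference bran) types,
    six-level processed-meat and beef frequency scales (reference never),
    and continuous age (40–70 years) and BMI (18.5–50 kg/m²).  Level
    probabilities are plausible population defaults; they are tunable and
    make no claim to match any particular cohort's marginals.
    """
    schema = [
        _binary("loneliness_isolation", 0.18),
        _binary("seen_psychiatrist", 0.12),
        _binary("sleeplessness_insomnia", 0.28),
        _binary("fed_up_feelings", 0.40),
        _binary("tense_highly_strung", 0.17),
        _binary("sleep_duration_7_8h", 0.55),
        _binary("nap_during_day", 0.20),
        _binary("difficulty_getting_up", 0.30),
        _binary("plays_computer_games", 0.10),
        _binary("current_tobacco_smoking", 0.10),
        VariableSpec(
            name="smoking_status", scale="nominal",
            levels=["never", "previous", "current"], reference_level="never",
            cox_encoding="dummy_set", ann_encoding="binary_indicator",
            gen_params={"probs": [0.55, 0.35, 0.10]}, ann_collapse="ever",
        ),
        VariableSpec(
            name="salt_added_to_food", scale="ordinal",
            levels=["never_rarely", "sometimes", "usually", "always"],
            reference_level="never_rarely",
            cox_encoding="ordinal_numeric", ann_encoding="one_hot",
            gen_params={"probs": [0.55, 0.25, 0.12, 0.08]},
        ),
        _binary("cheese_intake", 0.85),
        VariableSpec(
            name="bread_type", scale="nominal",
            levels=["wholewheat", "white", "brown", "other"],
            reference_level="wholewheat",
            cox_encoding="dummy_set", ann_encoding="one_hot",
            gen_params={"probs": [0.45, 0.30, 0.18, 0.07]},
        ),
        VariableSpec(
            name="cereal_type", scale="nominal",
            levels=["bran", "biscuit", "oat", "muesli", "sugary"],
            reference_level="bran",
            cox_encoding="dummy_set", ann_encoding="one_hot",
            gen_params={"probs": [0.20, 0.30, 0.20, 0.15, 0.15]},
        ),
        VariableSpec(
            name="processed_meat_intake", scale="ordinal",
            levels=list(MEAT_LEVELS), reference_level="never",
            cox_encoding="dummy_set", ann_encoding="binary_indicator",
            gen_params={"probs": [0.10, 0.30, 0.30, 0.25, 0.04, 0.01]},
            ann_collapse="top_level",
        ),
        VariableSpec(
            name="beef_intake", scale="ordinal",
            levels=list(MEAT_LEVELS), reference_level="never",
            cox_encoding="dummy_set", ann_encoding="binary_indicator",
            gen_params={"probs": [0.12, 0.35, 0.30, 0.20, 0.02, 0.01]},
            ann_collapse="top_level",
        ),
        VariableSpec(
            name="age", scale="continuous",
            cox_encoding="dummy_set", ann_encoding="minmax_continuous",
            gen_params={"range": [40.0, 70.0]},
            cox_bins={"edges": [40, 50, 60, 70.0001],
                      "labels": ["40_49", "50_59", "60_70"],
                      "reference": "40_49"},
        ),
        VariableSpec(
            name="bmi", scale="continuous",
            cox_encoding="dummy_set", ann_encoding="minmax_continuous",
            gen_params={"range": [18.5, 50.0]},
            cox_bins={"edges": [18.5, 25, 30, 35, 40, 50.0001],
                      "labels": ["18.5_24.9", "25_29.9", "30_34.9",
                                 "35_39.9", "40_50"],
                      "reference": "18.5_24.9"},
        ),
    ]
    return schema


# ----------------------------------------------------------------------
# (De)serialization — sidecar JSON schema files
# ----------------------------------------------------------------------

def schema_to_json(schema: list[VariableSpec]) -> list[dict]:
    return [asdict(s) for s in schema]


def schema_from_json(data: list[dict]) -> list[VariableSpec]:
    return [VariableSpec(**d) for d in data]
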