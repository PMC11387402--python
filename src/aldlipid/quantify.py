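"""Internal-standard semi-quantification and isotope-dilution assays.

Untargeted lipidomics abundances are semi-quantitative: each analyte peak
area is divided by the peak area of its lipid class's spiked internal
standard (IS) in the same sample and scaled by the plasma-equivalent IS
concentration (amount spiked / plasma volume). The result is expressed in
arbitrary units (A.U.); because every sample is divided by a same-sample IS
area, any per-sample multiplicative response factor cancels.

The targeted assays (LPC(26:0) against D4-LPC(26:0); total C22:0/C24:0/
C26:0 against the deuterated fatty acids) are classical isotope dilution:
concentration = (analyte area / labeled-standard area) x spiked amount /
plasma volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import InternalStandardSpec, parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "semiquantify",
    "InternalStandardNormalizer",
    "isotope_dilution_conc",
    "UNIT_SCALE",
]

# multiplicative factors from nmol/uL (= mmol/L) to the named unit
UNIT_SCALE = {
    "mmol/L": 1.0,
    "umol/L": 1e3,
    "nmol/L": 1e6,
}


@dataclass
class AbundanceTable:
    """Lipid x sample semi-quantitative abundances with IS provenance."""

    data: pd.DataFrame
    units: str = "A.U."
    is_used: dict[str, str] = field(default_factory=dict)
    flagged: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("abundances must be nonnegative")


def semiquantify(
    areas: pd.DataFrame,
    lipid_class: Mapping[str, str] | None,
    is_areas: pd.DataFrame,
    is_specs: Mapping[str, InternalStandardSpec],
    unit_scale: float = 1.0,
) -> AbundanceTable:
    """Convert a lipid x sample peak-area table to A.U. abundances.

    Parameters
    ----------
    areas : DataFrame, lipid rows x sample columns
    lipid_class : mapping lipid name -> class code; parsed from the row
        names when None.
    is_areas : DataFrame, class code rows x sample columns, the internal
        standard peak areas per sample.
    is_specs : mapping class code -> InternalStandardSpec.
    unit_scale : extra multiplicative factor on the A.U. scale.

    A missing or nonpositive IS area flags that (class, sample) cell;
    affected abundances become NaN, never zero.
    """
    if lipid_class is None:
        lipid_class = {
            name: parse_lipid_name(str(name)).class_code for name in areas.index
        }
    missing = {lipid_class[name] for name in areas.index} - set(is_specs)
    if missing:
        raise ValueError(f"no internal standard spec for classes {sorted(missing)}")

    out = pd.DataFrame(np.nan, index=areas.index, columns=areas.columns)
    flagged: list[tuple[str, str]] = []
    is_used: dict[str, str] = {}
    for name in areas.index:
        cls = lipid_class[name]
        spec = is_specs[cls]
        is_used[str(name)] = spec.species
        if cls not in is_areas.index:
            raise ValueError(f"no IS areas for class {cls}")
        denom = is_areas.loc[cls].reindex(areas.columns).to_numpy(dtype=float)
        bad = ~(denom > 0)
        if bad.any():
            for sample in areas.columns[bad]:
                flagged.append((cls, str(sample)))
            logger.warning(
                "class %s: nonpositive IS area in %d sample(s); abundances "
                "set missing",
                cls,
                int(bad.sum()),
            )
        ratio = areas.loc[name].to_numpy(dtype=float) / np.where(bad, np.nan, denom)
        out.loc[name] = ratio * spec.concentration * unit_scale
    dedup = sorted(set(flagged))
    return AbundanceTable(out.clip(lower=0), "A.U.", is_used, dedup)


class InternalStandardNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer for class-IS semi-quantification.

    ``fit`` records the IS specs and per-sample IS areas; ``transform``
    maps a peak-area table (lipid rows x sample columns) to A.U.
    abundances.
    """

    def __init__(self, is_specs=None, unit_scale: float = 1.0):
        self.is_specs = is_specs
        self.unit_scale = unit_scale

    def fit(self, X: pd.DataFrame, y=None, is_areas: pd.DataFrame | None = None):
        if is_areas is None:
            raise ValueError("fit requires is_areas (class x sample IS areas)")
        specs = self.is_specs
        if specs is None:
            from .chem import default_templates

            specs = {
                code: tpl.internal_standard
                for code, tpl in default_templates().items()
                if tpl.internal_standard is not None
            }
        self.is_specs_ = dict(specs)
        self.is_areas_ = is_areas
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "is_specs_"):
            raise ValueError("InternalStandardNormalizer is not fitted")
        table = semiquantify(X, None, self.is_areas_, self.is_specs_, self.unit_scale)
        self.last_result_ = table
        return table.data


def isotope_dilution_conc(
    analyte_area,
    labeled_is_area,
    is_amount_nmol: float,
    plasma_volume_ul: float,
    out_unit: str = "nmol/L",
):
    """Isotope-dilution concentration from an analyte/label area ratio.

    concentration = (analyte area / labeled area) * amount / volume, with
    amount in nmol and volume in uL, i.e. a base scale of nmol/uL = mmol/L,
    converted to ``out_unit``. Accepts scalars or arrays; vectorized.
    """
    if out_unit not in UNIT_SCALE:
        raise ValueError(f"unknown unit {out_unit!r}; use one of {list(UNIT_SCALE)}")
    if is_amount_nmol <= 0 or plasma_volume_ul <= 0:
        raise ValueError("IS amount and plasma volume must be positive")
    labeled = np.asarray(labeled_is_area, dtype=float)
    if (labeled <= 0).any():
        raise ValueError("labeled internal-standard area must be positive")
    ratio = np.asarray(analyte_area, dtype=float) / labeled
    conc = ratio * (is_amount_nmol / plasma_volume_ul) * UNIT_SCALE[out_unit]
    return conc if conc.ndim else float(conc)
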