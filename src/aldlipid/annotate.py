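"""Accurate-mass annotation of LC-MS features against an m/z catalog.

Each feature (observed m/z, polarity, optional retention time) is matched
against every catalog entry inside a ppm window; exactly one hit is
accepted per feature — smallest absolute ppm error, ties broken by adduct
priority and then species name — and unmatched features are kept, flagged
unannotated, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import LipidClassTemplate, MzCatalog, build_catalog, parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "AnnotationHit",
    "annotate",
    "MassAnnotator",
    "feature_table_from_names",
]

#: tie-break priority when two adducts give the same |ppm| error
DEFAULT_ADDUCT_PRIORITY = ("[M+H]+", "[M+NH4]+", "[M+Na]+", "[M-H]-", "[M+HCOO]-")


@dataclass(frozen=True)
class Feature:
    """One aligned LC-MS feature with per-sample peak areas."""

    feature_id: str
    mz: float
    polarity: str
    rt: float | None = None
    areas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: m/z must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"{self.feature_id}: bad polarity {self.polarity!r}")
        if any(v < 0 for v in self.areas.values() if v == v):
            raise ValueError(f"{self.feature_id}: negative peak area")


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    species: str | None
    class_code: str | None
    adduct: str | None
    ppm_error: float | None
    accepted: bool

    @property
    def annotated(self) -> bool:
        return self.species is not None


def _ppm(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


def annotate(
    features: Iterable[Feature],
    catalog: MzCatalog,
    tol_ppm: float = 5.0,
    rt_windows: Mapping[str, tuple[float, float]] | None = None,
    adduct_priority: Sequence[str] = DEFAULT_ADDUCT_PRIORITY,
) -> list[AnnotationHit]:
    """Assign one lipid identity per feature by accurate mass.

    All catalog entries within ``tol_ppm`` of a feature (and, when
    ``rt_windows`` provides a window for the candidate's class, with the
    feature's retention time inside it) are candidates; the accepted hit
    minimizes ``|ppm error|``, ties broken by ``adduct_priority`` then
    lexicographic species name. Features without any candidate come back
    with ``accepted=False`` and no species.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    prio = {name: i for i, name in enumerate(adduct_priority)}
    hits: list[AnnotationHit] = []
    for feat in features:
        cands = catalog.query(feat.mz, tol_ppm, polarity=feat.polarity)
        if rt_windows is not None and feat.rt is not None and len(cands):
            keep = [
                cls not in rt_windows
                or rt_windows[cls][0] <= feat.rt <= rt_windows[cls][1]
                for cls in cands["class_code"]
            ]
            cands = cands[np.asarray(keep, dtype=bool)]
        if not len(cands):
            if len(catalog.query(feat.mz, tol_ppm)) > len(cands):
                logger.warning(
                    "feature %s: catalog matches exist only in the other "
                    "polarity; skipped",
                    feat.feature_id,
                )
            hits.append(AnnotationHit(feat.feature_id, None, None, None, None, False))
            continue
        ppm = _ppm(feat.mz, cands["mz"].to_numpy())
        order = sorted(
            range(len(cands)),
            key=lambda i: (
                abs(ppm[i]),
                prio.get(cands["adduct"].iloc[i], len(prio)),
                cands["name"].iloc[i],
            ),
        )
        best = order[0]
        hits.append(
            AnnotationHit(
                feat.feature_id,
                cands["name"].iloc[best],
                cands["class_code"].iloc[best],
                cands["adduct"].iloc[best],
                float(ppm[best]),
                True,
            )
        )
    return hits


def hits_to_frame(hits: Iterable[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": h.feature_id,
                "species": h.species,
                "class_code": h.class_code,
                "adduct": h.adduct,
                "ppm_error": h.ppm_error,
                "accepted": h.accepted,
            }
            for h in hits
        ]
    )


class MassAnnotator(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping accurate-mass annotation.

    Parameters
    ----------
    templates : sequence of LipidClassTemplate, optional
        Class templates expanded into the catalog at ``fit``; defaults to
        the packaged class configuration.
    tol_ppm : float
        Mass-accuracy window in parts per million.
    rt_windows : mapping class -> (lo, hi) minutes, optional
    """

    def __init__(self, templates=None, tol_ppm: float = 5.0, rt_windows=None):
        self.templates = templates
        self.tol_ppm = tol_ppm
        self.rt_windows = rt_windows

    def fit(self, X=None, y=None) -> "MassAnnotator":
        from .chem import default_templates

        templates = self.templates
        if templates is None:
            templates = list(default_templates().values())
        self.catalog_ = build_catalog(templates)
        return self

    def transform(self, X: Iterable[Feature]) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            raise ValueError("MassAnnotator is not fitted; call fit() first")
        return hits_to_frame(
            annotate(X, self.catalog_, self.tol_ppm, self.rt_windows)
        )


def feature_table_from_names(
    named_table: pd.DataFrame, polarity: str = "positive"
) -> tuple[list[Feature], list[AnnotationHit], list[str]]:
    """Turn a lipid-name-keyed abundance table into pre-annotated features.

    Supplementary-style tables carry lipid names, not m/z, as row keys; each
    parseable row becomes a feature with a synthetic id and an accepted hit
    (ppm error 0, no mass lookup). Unparseable row labels are returned in a
    rejects list and the remaining rows are processed.
    """
    features: list[Feature] = []
    hits: list[AnnotationHit] = []
    rejects: list[str] = []
    for label, row in named_table.iterrows():
        try:
            parsed = parse_lipid_name(str(label))
        except ValueError:
            rejects.append(str(label))
            continue
        feat = Feature(
            feature_id=str(label),
            mz=1.0,  # placeholder; identity comes from the name
            polarity=polarity,
            areas=row.to_dict(),
        )
        features.append(feat)
        hits.append(
            AnnotationHit(str(label), str(label), parsed.class_code, None, 0.0, True)
        )
    if rejects:
        logger.warning("feature_table_from_names: %d unparseable rows", len(rejects))
    return features, hits, rejects
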