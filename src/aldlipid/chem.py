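"""Lipid-class formula expansion and accurate-mass arithmetic.

Lipid classes are described by generic elemental formulas in which the
radyl ("R") chains are left open. Expanding a class over a grid of total
acyl-carbon numbers ``n`` and total double-bond counts ``d`` yields
sum-composition species such as ``LPC(26:0)``; each species gets a neutral
monoisotopic mass and, per adduct, an m/z value. The expansion is linear in
(n, d): each element count is ``a + b*n + c*d``, e.g. for
lysophosphatidylcholine C(n+8) H(2n+18-2d) N O7 P, which is the unique rule
consistent with glycerophosphocholine (C8H20NO6P) plus one fatty acid
CnH(2n-2d)O2 minus water.
"""

from __future__ import annotations

import importlib.resources
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ELEMENT_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "AdductIon",
    "DEFAULT_ADDUCTS",
    "LipidClassTemplate",
    "LipidSpecies",
    "MzCatalog",
    "InvalidTemplateError",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "expand_class",
    "build_catalog",
    "parse_lipid_name",
    "LipidName",
    "load_templates",
    "default_templates",
]

# Monoisotopic atomic masses in Da (most abundant isotope), CODATA/NIST.
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.01410177785,  # deuterium, for isotope-labeled internal standards
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidTemplateError(ValueError):
    """A class formula rule produced a negative element count."""


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C34H70NO7P"`` into ``{"C": 34, "H": 70, ...}``."""
    if isinstance(formula, Mapping):
        return {el: int(k) for el, k in formula.items() if k}
    counts: Counter[str] = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"malformed formula {formula!r} at {formula[pos:match.start()]!r}"
            )
        pos = match.end()
        counts[match.group(1)] += int(match.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at {formula[pos:]!r}")
    return dict(counts)


def formula_to_string(formula: Mapping[str, int]) -> str:
    """Hill-ish ordering: C, H, then other elements alphabetically."""
    order = sorted(formula, key=lambda el: (el not in ("C", "H"), el != "C", el))
    parts = []
    for el in order:
        k = formula[el]
        if k == 0:
            continue
        parts.append(el if k == 1 else f"{el}{k}")
    return "".join(parts)


def monoisotopic_mass(
    formula: str | Mapping[str, int],
    masses: Mapping[str, float] | None = None,
) -> float:
    """Neutral monoisotopic mass (Da) of an elemental formula."""
    masses = ELEMENT_MASS if masses is None else masses
    counts = parse_formula(formula)
    total = 0.0
    for el, k in counts.items():
        if el not in masses:
            raise ValueError(f"unknown element symbol {el!r}")
        total += masses[el] * k
    return total


@dataclass(frozen=True)
class AdductIon:
    """A charged adduct form of a neutral lipid.

    ``mass_shift`` is the signed, electron-corrected mass added to the
    neutral molecule; ``charge`` is the signed ion charge.
    """

    name: str
    mass_shift: float
    charge: int
    polarity: str

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"adduct {self.name}: charge must be nonzero")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"adduct {self.name}: bad polarity {self.polarity!r}")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError(
                f"adduct {self.name}: polarity {self.polarity} inconsistent "
                f"with charge {self.charge:+d}"
            )

    def mz(self, neutral_mass: float) -> float:
        return adduct_mz(neutral_mass, self)


def adduct_mz(neutral_mass: float, adduct: AdductIon) -> float:
    """m/z = (M + shift) / |z| for a singly- or multiply-charged adduct."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    return (neutral_mass + adduct.mass_shift) / abs(adduct.charge)


DEFAULT_ADDUCTS: dict[str, AdductIon] = {
    "[M+H]+": AdductIon("[M+H]+", PROTON_MASS, 1, "positive"),
    "[M+NH4]+": AdductIon(
        "[M+NH4]+", monoisotopic_mass("NH4") - ELECTRON_MASS, 1, "positive"
    ),
    "[M+Na]+": AdductIon(
        "[M+Na]+", ELEMENT_MASS["Na"] - ELECTRON_MASS, 1, "positive"
    ),
    "[M-H]-": AdductIon("[M-H]-", -PROTON_MASS, -1, "negative"),
    "[M+HCOO]-": AdductIon(
        "[M+HCOO]-", monoisotopic_mass("CH2O2") - PROTON_MASS, -1, "negative"
    ),
}


@dataclass(frozen=True)
class InternalStandardSpec:
    """Spiked internal standard for one lipid class."""

    class_code: str
    species: str
    amount_nmol: float
    plasma_volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if self.amount_nmol <= 0:
            raise ValueError(f"{self.class_code}: IS amount must be > 0")
        if self.plasma_volume_ul <= 0:
            raise ValueError(f"{self.class_code}: plasma volume must be > 0")

    @property
    def concentration(self) -> float:
        """Plasma-equivalent IS concentration, nmol/µL (≡ mmol/L)."""
        return self.amount_nmol / self.plasma_volume_ul


@dataclass(frozen=True)
class LipidClassTemplate:
    """Generic class formula with open radyl slots.

    ``coefficients`` maps element -> (const, per_carbon, per_double_bond);
    the species formula at sum composition (n, d) has
    ``const + per_carbon*n + per_double_bond*d`` atoms of that element.
    """

    class_code: str
    radyl_count: int
    coefficients: Mapping[str, tuple[int, int, int]]
    carbon_range: tuple[int, int]
    db_range: tuple[int, int]
    adducts: tuple[AdductIon, ...]
    internal_standard: InternalStandardSpec | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.radyl_count <= 4:
            raise ValueError(f"{self.class_code}: radyl_count must be 1-4")
        if self.carbon_range[0] < 2 * self.radyl_count:
            raise ValueError(
                f"{self.class_code}: carbon_range min {self.carbon_range[0]} "
                f"< 2 x radyl_count"
            )
        if self.carbon_range[0] > self.carbon_range[1] or self.db_range[0] > self.db_range[1]:
            raise ValueError(f"{self.class_code}: empty (n, d) range")

    def formula(self, n: int, d: int) -> dict[str, int]:
        out = {}
        for el, (a, b, c) in self.coefficients.items():
            k = a + b * n + c * d
            if k < 0:
                raise InvalidTemplateError(
                    f"{self.class_code}({n}:{d}): element {el} count {k} < 0"
                )
            if k:
                out[el] = k
        return out


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition lipid species, e.g. PC(44:2)."""

    class_code: str
    total_carbons: int
    total_double_bonds: int
    formula: Mapping[str, int]
    mass: float
    isotope_label: str | None = None

    @property
    def name(self) -> str:
        label = f"{self.isotope_label}-" if self.isotope_label else ""
        return f"{label}{self.class_code}({self.total_carbons}:{self.total_double_bonds})"


def make_species(
    template: LipidClassTemplate, n: int, d: int, isotope_label: str | None = None
) -> LipidSpecies:
    formula = template.formula(n, d)
    if isotope_label:
        formula = apply_isotope_label(formula, isotope_label)
    return LipidSpecies(
        template.class_code, n, d, formula, monoisotopic_mass(formula), isotope_label
    )


def apply_isotope_label(formula: Mapping[str, int], label: str) -> dict[str, int]:
    """Substitute k protium atoms with deuterium for a ``Dk`` label."""
    match = re.fullmatch(r"D(\d+)", label)
    if not match:
        raise ValueError(f"unsupported isotope label {label!r}")
    k = int(match.group(1))
    out = dict(formula)
    if out.get("H", 0) < k:
        raise ValueError(f"cannot substitute {k} H in {formula_to_string(formula)}")
    out["H"] -= k
    out["D"] = out.get("D", 0) + k
    return out


def expand_class(template: LipidClassTemplate) -> list[LipidSpecies]:
    """One species per (n, d) grid point of the class template."""
    n_lo, n_hi = template.carbon_range
    d_lo, d_hi = template.db_range
    species = []
    for n in range(n_lo, n_hi + 1):
        for d in range(d_lo, d_hi + 1):
            species.append(make_species(template, n, d))
    return species


# ---------------------------------------------------------------------------
# Lipid-name parsing


class LipidName(NamedTuple):
    class_code: str
    total_carbons: int
    total_double_bonds: int
    isomer: str | None = None
    isotope_label: str | None = None

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.class_code, self.total_carbons, self.total_double_bonds)


_NAME_RE = re.compile(
    r"^\s*(?:(?P<label>D\d+|\d+H\d+)-)?"
    r"(?:(?P<isomer>[12])-acyl[ -])?"
    r"(?P<cls>[A-Za-z][A-Za-z0-9]*?)\s*\((?P<chains>[^)]*)\)\s*$"
)
_CHAIN_RE = re.compile(r"^(?P<prefix>[dtme]|O-|P-)?(?P<n>\d+):(?P<d>\d+)$")


def parse_lipid_name(name: str) -> LipidName:
    """Parse sum-composition or per-chain lipid names.

    ``"PC(44:2)"`` -> (PC, 44, 2); ``"TG(14:0/14:0/14:0)"`` -> (TG, 42, 0);
    sphingoid chains like ``SM(d18:1/12:0)`` sum carbons and double bonds
    across chains. A leading ``1-acyl``/``2-acyl`` prefix is preserved as an
    isomer tag and a ``D4-`` style prefix as an isotope label.
    """
    match = _NAME_RE.match(name)
    if not match:
        raise ValueError(f"cannot parse lipid name {name!r}")
    chains = match.group("chains").strip()
    if not chains:
        raise ValueError(f"cannot parse lipid name {name!r}: empty composition")
    n = d = 0
    for chain in chains.split("/"):
        chain = chain.strip()
        cmatch = _CHAIN_RE.match(chain)
        if not cmatch:
            raise ValueError(f"cannot parse lipid name {name!r}: bad chain {chain!r}")
        n += int(cmatch.group("n"))
        d += int(cmatch.group("d"))
    isomer = match.group("isomer")
    return LipidName(
        match.group("cls"),
        n,
        d,
        isomer=f"{isomer}-acyl" if isomer else None,
        isotope_label=match.group("label"),
    )


# ---------------------------------------------------------------------------
# m/z catalog


class MzCatalog:
    """Sorted (species x adduct) -> m/z catalog with ppm-window queries."""

    COLUMNS = (
        "class_code",
        "name",
        "formula",
        "neutral_mass",
        "adduct",
        "charge",
        "polarity",
        "mz",
    )

    def __init__(self, entries: pd.DataFrame):
        missing = set(self.COLUMNS) - set(entries.columns)
        if missing:
            raise ValueError(f"catalog missing columns {sorted(missing)}")
        dup = entries.duplicated(subset=["name", "adduct"])
        if dup.any():
            pairs = entries.loc[dup, ["name", "adduct"]].to_records(index=False)
            raise ValueError(f"duplicate (species, adduct) entries: {list(pairs)[:5]}")
        if (entries["mz"] <= 0).any():
            raise ValueError("catalog contains nonpositive m/z")
        self.entries = (
            entries.loc[:, list(self.COLUMNS)]
            .sort_values(["mz", "name", "adduct"], kind="mergesort")
            .reset_index(drop=True)
        )
        self._mz = self.entries["mz"].to_numpy()

    def __len__(self) -> int:
        return len(self.entries)

    def query(
        self, mz: float, tol_ppm: float, polarity: str | None = None
    ) -> pd.DataFrame:
        """All entries within ``tol_ppm`` of ``mz`` (window relative to query)."""
        if tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        half = mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(self._mz, mz - half, side="left"))
        hi = int(np.searchsorted(self._mz, mz + half, side="right"))
        hits = self.entries.iloc[lo:hi]
        if polarity is not None:
            hits = hits[hits["polarity"] == polarity]
        return hits

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path) -> "MzCatalog":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def build_catalog(templates: Iterable[LipidClassTemplate]) -> MzCatalog:
    """Expand every template and tabulate all adduct m/z values."""
    templates = list(templates)
    if not templates:
        raise ValueError("at least one class template required")
    rows = []
    for tpl in templates:
        for sp in expand_class(tpl):
            for adduct in tpl.adducts:
                rows.append(
                    {
                        "class_code": sp.class_code,
                        "name": sp.name,
                        "formula": formula_to_string(sp.formula),
                        "neutral_mass": sp.mass,
                        "adduct": adduct.name,
                        "charge": adduct.charge,
                        "polarity": adduct.polarity,
                        "mz": adduct_mz(sp.mass, adduct),
                    }
                )
    return MzCatalog(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Template configuration


def _template_from_config(code: str, cfg: Mapping) -> LipidClassTemplate:
    coeffs = {
        el: tuple(int(x) for x in abc) for el, abc in cfg["formula"].items()
    }
    adduct_names = cfg.get("adducts", list(DEFAULT_ADDUCTS))
    adducts = tuple(DEFAULT_ADDUCTS[a] for a in adduct_names)
    is_spec = None
    if cfg.get("internal_standard"):
        isc = cfg["internal_standard"]
        is_spec = InternalStandardSpec(
            code,
            isc["species"],
            float(isc["amount_nmol"]),
            float(isc.get("plasma_volume_ul", 20.0)),
        )
    return LipidClassTemplate(
        class_code=code,
        radyl_count=int(cfg["radyl_count"]),
        coefficients=coeffs,
        carbon_range=tuple(cfg["carbon_range"]),
        db_range=tuple(cfg["db_range"]),
        adducts=adducts,
        internal_standard=is_spec,
    )


def load_templates(source) -> dict[str, LipidClassTemplate]:
    """Load class templates from a YAML path, file object, or mapping."""
    if isinstance(source, Mapping):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    return {
        code: _template_from_config(code, sub) for code, sub in cfg["classes"].items()
    }


def default_templates() -> dict[str, LipidClassTemplate]:
    """The packaged lipid-class catalog configuration."""
    ref = importlib.resources.files("aldlipid").joinpath("data/lipid_classes.yaml")
    with ref.open() as fh:
        return load_templates(fh)
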