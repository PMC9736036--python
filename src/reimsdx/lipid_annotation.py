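"""Offline lipid annotation for negative-ion REIMS peaks.

Annotation proceeds in two stages, mirroring the usual LipidMaps-style
workflow for ambient ionisation lipidomics:

1. *Precursor matching*: a query m/z is compared against theoretical adduct
   m/z values ([M−H]⁻, [M+Cl]⁻, and optionally [M−NH3−H]⁻) computed from
   elemental formulas by summing monoisotopic atomic masses. Matches within
   a mass tolerance (default ±0.1 Th, the tolerance typically used when
   searching Q-ToF REIMS data) are returned as candidates.

2. *MS/MS refinement*: observed daughter ions are compared against the
   fatty-acyl carboxylate anions [RCOO]⁻ predicted from each candidate's
   chain composition; candidates are re-ranked by the number of supporting
   fragments. Ether (O-) and plasmalogen (P-) chains are vinyl/alkyl ethers
   and do not yield carboxylate fragments; sum compositions like "PA(36:2)"
   have unknown chains and receive zero support (never an error).

The bundled panel contains the curated glycerophospholipid / ceramide
species relevant to endometrial tissue classification plus a set of common
even-chain diacyl species, so annotation is fully offline and hermetic.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Adduct",
    "LipidFormula",
    "AnnotationCandidate",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "annotate_peak",
    "refine_with_fragments",
    "acyl_carboxylate_mzs",
    "curated_panel",
    "extended_panel",
    "default_panel",
    "write_panel_csv",
    "read_panel_csv",
]

# Monoisotopic atomic masses (Da). Values fixed here rather than taken from a
# periodic-table library so that every reported m/z is reproducible from this
# table alone.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "Cl": 34.96885268,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858
#: Neutral ammonia, for the deaminated adduct.
NH3_MASS = MONOISOTOPIC_MASS["N"] + 3 * MONOISOTOPIC_MASS["H"]


class Adduct(str, Enum):
    """Negative-mode adducts considered during precursor matching."""

    M_MINUS_H = "[M-H]-"
    M_PLUS_CL = "[M+Cl]-"
    M_MINUS_NH3_MINUS_H = "[M-NH3-H]-"


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _mass(formula: str) -> float:
    total = 0.0
    for m in _FORMULA_TOKEN.finditer(formula):
        total += MONOISOTOPIC_MASS[m.group(1)] * (int(m.group(2)) if m.group(2) else 1)
    return total


#: Calibration reference ions, computed from their formulas (printed in the
#: field to three decimals as 554.262 and 699.497 Th).
EXTERNAL_LOCKMASS_MZ = _mass("C28H37N5O7") - PROTON_MASS  # leucine enkephalin [M−H]⁻
INTERNAL_LOCKMASS_MZ = _mass("C39H73O8P") - PROTON_MASS   # PA(36:2) [M−H]⁻


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``"C39H73O8P"``) into counts."""
    if not formula or not formula.strip():
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula.strip()):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_to_string(elements: Mapping[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(e for e in elements if e not in ("C", "H"))
    out = []
    for e in order:
        n = elements.get(e, 0)
        if n:
            out.append(e + (str(n) if n > 1 else ""))
    return "".join(out)


@dataclass(frozen=True)
class LipidFormula:
    """A lipid species with an elemental formula and optional chain detail.

    ``chains`` encodes acyl/alkyl composition as "/"-separated tokens, e.g.
    ``"P-16:0/20:4"``; a ``+O`` suffix marks an extra hydroxyl on that chain
    and a ``d``/``t`` prefix a sphingoid base. ``None`` means only the sum
    composition is known (no fragment prediction possible).
    """

    name: str
    elements: Mapping[str, int]
    lipid_class: str = "other"
    chains: str | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"lipid {self.name!r}: empty elemental formula")
        for e, n in self.elements.items():
            if e not in MONOISOTOPIC_MASS:
                raise ValueError(f"lipid {self.name!r}: unknown element {e!r}")
            if not (isinstance(n, int) and n > 0):
                raise ValueError(f"lipid {self.name!r}: count for {e} must be a positive integer")

    @property
    def formula(self) -> str:
        return formula_to_string(self.elements)


@dataclass
class AnnotationCandidate:
    query_mz: float
    lipid: LipidFormula
    adduct: Adduct
    theoretical_mz: float
    mass_error: float  # query − theoretical, Th
    fragment_support: int = 0


def monoisotopic_mass(f: LipidFormula | Mapping[str, int] | str) -> float:
    """Monoisotopic neutral mass (Da) from summed atomic masses."""
    if isinstance(f, LipidFormula):
        elements: Mapping[str, int] = f.elements
    elif isinstance(f, str):
        elements = parse_formula(f)
    else:
        elements = f
    if not elements:
        raise ValueError("empty elemental formula")
    total = 0.0
    for element, count in elements.items():
        try:
            total += count * MONOISOTOPIC_MASS[element]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of a singly charged negative adduct of a neutral of given mass.

    Deprotonation removes a proton and keeps the electron; chloride addition
    adds both the Cl atom mass and one electron. The ~0.5 mDa electron term
    is invisible at ±0.1 Th but is applied consistently.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    adduct = Adduct(adduct)
    if adduct is Adduct.M_MINUS_H:
        return neutral_mass - PROTON_MASS
    if adduct is Adduct.M_PLUS_CL:
        return neutral_mass + MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS
    if adduct is Adduct.M_MINUS_NH3_MINUS_H:
        return neutral_mass - NH3_MASS - PROTON_MASS
    raise ValueError(f"unknown adduct {adduct!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Bundled panel
# ---------------------------------------------------------------------------

#: Curated species with MS/MS-supported (or literature) chain assignments.
#: Each tuple: (name, formula, class, chains, preferred adduct).
_CURATED: Sequence[tuple[str, str, str, str | None, Adduct]] = (
    ("Cer(d18:1/18:0)", "C36H71NO3", "Cer", "d18:1/18:0", Adduct.M_PLUS_CL),
    ("PA(34:2)", "C37H69O8P", "PA", None, Adduct.M_MINUS_H),
    ("PG(O-16:0/14:0)", "C36H73O9P", "PG", "O-16:0/14:0", Adduct.M_MINUS_H),
    ("PA(36:2)", "C39H73O8P", "PA", None, Adduct.M_MINUS_H),
    ("PE(P-16:0/20:4)", "C41H74NO7P", "PE", "P-16:0/20:4", Adduct.M_MINUS_H),
    ("PE(P-16:0/20:4)(12OH)", "C41H74NO8P", "PE", "P-16:0/20:4+O", Adduct.M_MINUS_H),
    ("PE(18:0/20:4)", "C43H78NO8P", "PE", "18:0/20:4", Adduct.M_MINUS_H),
    ("PS(36:2)", "C42H78NO10P", "PS", None, Adduct.M_MINUS_H),
    ("PC(O-18:0/20:4)", "C46H86NO7P", "PC", "O-18:0/20:4", Adduct.M_MINUS_H),
    # Plasmalogen PE consistent with the 750.57 peak (diacyl PE(38:4) is not).
    ("PE(P-18:0/20:4)", "C43H78NO7P", "PE", "P-18:0/20:4", Adduct.M_MINUS_H),
    # Diacyl isomer of the 738.51 peak; distinguishable only by fragments.
    ("PE(16:0/20:4)", "C41H74NO8P", "PE", "16:0/20:4", Adduct.M_MINUS_H),
)

# Diacyl glycerophospholipid formula rules: for total acyl carbons c and
# double bonds d the neutral formula is C(c+kC) H(2c−2d+kH) N(kN) O(kO) P.
_DIACYL_RULES: Mapping[str, tuple[int, int, int, int]] = {
    # class: (kC, kH, kN, kO)
    "PC": (8, 16, 1, 8),
    "PE": (5, 10, 1, 8),
    "PA": (3, 5, 0, 8),
    "PS": (6, 10, 1, 10),
    "PG": (6, 11, 0, 10),
}


def diacyl_formula(lipid_class: str, carbons: int, double_bonds: int) -> dict[str, int]:
    """Elemental formula of a diacyl glycerophospholipid sum composition."""
    try:
        kc, kh, kn, ko = _DIACYL_RULES[lipid_class]
    except KeyError:
        raise ValueError(f"no diacyl formula rule for class {lipid_class!r}") from None
    elements = {"C": carbons + kc, "H": 2 * carbons - 2 * double_bonds + kh, "O": ko, "P": 1}
    if kn:
        elements["N"] = kn
    return elements


def curated_panel() -> list[LipidFormula]:
    """The curated species (with chain detail where MS/MS supports it)."""
    return [LipidFormula(n, parse_formula(f), c, ch) for n, f, c, ch, _ in _CURATED]


def curated_adducts() -> dict[str, Adduct]:
    """Preferred (observed) adduct for each curated species name."""
    return {n: a for n, f, c, ch, a in _CURATED}


def extended_panel() -> list[LipidFormula]:
    """Curated species plus common even-chain diacyl PC/PE/PA/PS/PG.

    The generated sum compositions cover total acyl carbons 30–44 (even) and
    0–4 double bonds; only even fatty chains are admitted, matching the usual
    biological prior for mammalian glycerophospholipids.
    """
    panel = curated_panel()
    seen = {p.formula for p in panel}
    for cls in ("PC", "PE", "PA", "PS", "PG"):
        for carbons in range(30, 46, 2):
            for d in range(0, 5):
                elements = diacyl_formula(cls, carbons, d)
                key = formula_to_string(elements)
                if key in seen:
                    continue
                seen.add(key)
                panel.append(LipidFormula(f"{cls}({carbons}:{d})", elements, cls, None))
    return panel


def default_panel() -> list[LipidFormula]:
    return extended_panel()


def annotate_peak(
    query_mz: float,
    panel: Sequence[LipidFormula] | None = None,
    tolerance: float = 0.1,
    adducts: Iterable[Adduct | str] = (Adduct.M_MINUS_H, Adduct.M_PLUS_CL),
) -> list[AnnotationCandidate]:
    """All (lipid, adduct) pairs within ``tolerance`` Th of ``query_mz``.

    Candidates are sorted by absolute mass error, ties broken by lipid name
    for determinism. Returns an empty list when nothing matches.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if panel is None:
        panel = default_panel()
    adducts = [Adduct(a) for a in adducts]
    out: list[AnnotationCandidate] = []
    for lipid in panel:
        neutral = monoisotopic_mass(lipid)
        for adduct in adducts:
            theo = adduct_mz(neutral, adduct)
            err = query_mz - theo
            if abs(err) <= tolerance:
                out.append(AnnotationCandidate(query_mz, lipid, adduct, theo, err))
    out.sort(key=lambda c: (abs(c.mass_error), c.lipid.name, c.adduct.value))
    return out


_CHAIN_TOKEN = re.compile(r"^(?P<prefix>[OPdt]-?)?(?P<c>\d+):(?P<d>\d+)(?P<extra>\+\d*O)?$")


def acyl_carboxylate_mzs(chains: str | None) -> list[float]:
    """Theoretical [RCOO]⁻ m/z for each ester-linked acyl chain.

    Ether ("O-"), plasmalogen ("P-") and sphingoid ("d"/"t") chains produce
    no carboxylate anion and are skipped. A ``+O`` suffix (hydroxylated acyl)
    adds one oxygen to the fragment.
    """
    if not chains:
        return []
    out: list[float] = []
    for token in chains.split("/"):
        m = _CHAIN_TOKEN.match(token.strip())
        if m is None:
            continue
        prefix = m.group("prefix")
        if prefix:  # ether, plasmalogen or sphingoid backbone: no RCOO−
            continue
        c, d = int(m.group("c")), int(m.group("d"))
        extra_o = 1 if m.group("extra") else 0
        # fatty acid CcH(2c−2d)O2 (+ extra OH), deprotonated
        fa = {"C": c, "H": 2 * c - 2 * d, "O": 2 + extra_o}
        out.append(monoisotopic_mass(fa) - PROTON_MASS)
    return out


def refine_with_fragments(
    cands: Sequence[AnnotationCandidate],
    daughter_mzs: Sequence[float] | Sequence[tuple[float, float]],
    tolerance: float = 0.1,
    min_intensity: float = 5.0,
) -> list[AnnotationCandidate]:
    """Re-rank candidates by MS/MS fragment support.

    ``daughter_mzs`` may be plain m/z values or ``(mz, intensity)`` pairs; in
    the latter case fragments below ``min_intensity`` are discarded first.
    Each candidate's ``fragment_support`` counts daughters matching one of
    its predicted acyl carboxylate anions within ``tolerance``. Ordering is
    by support (descending) then absolute precursor mass error (ascending);
    with no usable daughters the input order is preserved.
    """
    if not cands:
        raise ValueError("candidate list must be nonempty")
    mzs: list[float] = []
    for d in daughter_mzs:
        if isinstance(d, (tuple, list)):
            mz, inten = d
            if inten >= min_intensity:
                mzs.append(float(mz))
        else:
            mzs.append(float(d))
    ranked = list(cands)
    for cand in ranked:
        frags = acyl_carboxylate_mzs(cand.lipid.chains)
        cand.fragment_support = sum(
            1 for obs in mzs if any(abs(obs - theo) <= tolerance for theo in frags)
        )
    ranked.sort(key=lambda c: (-c.fragment_support, abs(c.mass_error), c.lipid.name))
    return ranked


# ---------------------------------------------------------------------------
# Panel CSV interface
# ---------------------------------------------------------------------------

def write_panel_csv(panel: Sequence[LipidFormula], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "formula", "lipid_class", "chains"])
        for p in panel:
            w.writerow([p.name, p.formula, p.lipid_class, p.chains or ""])


def read_panel_csv(path) -> list[LipidFormula]:
    out: list[LipidFormula] = []
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.DictReader(fh)
        required = {"name", "formula", "lipid_class", "chains"}
        if r.fieldnames is None or not required.issubset(r.fieldnames):
            raise ValueError(f"panel CSV must have columns {sorted(required)}")
        for row in r:
            out.append(
                LipidFormula(
                    row["name"],
                    parse_formula(row["formula"]),
                    row["lipid_class"],
                    row["chains"] or None,
                )
            )
    return out
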