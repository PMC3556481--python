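"""Theoretical glycopeptide mass arithmetic.

Monoisotopic and average masses are computed from elemental
compositions via pyteomics' atomic-mass tables; residue masses for the
20 amino acids come from the standard residue compositions.  The adduct
model is protonation only: m/z = (M + z * m_proton) / z, the convention
of positive-ion ESI.  Fragment ions cover the b/y backbone series (with
glycan-retained and glycan-lost variants at annotated positions) and
the glycan oxonium series, including HexNAc m/z 204.087 and its
standard secondary ions.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

from .errors import ValidationError
from .epitopes import GlycopeptideEpitope
from .model import GlycanAlphabet, PeptideSequence

WATER_MONO = _pmass.calculate_mass(formula="H2O")
WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)
PROTON = _pmass.nist_mass["H+"][0][0]

_AA = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_MONO = {
    aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa]) for aa in _AA
}
RESIDUE_AVG = {
    aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
    for aa in _AA
}

# Oxonium-ion neutral compositions: the ion m/z is the neutral fragment
# mass plus one proton. HexNAc series: the classic 204.087 diagnostic
# plus its standard water / cross-ring losses (186.076, 168.066,
# 144.065, 138.055, 126.055); NeuAc series for sialylated states.
_HEXNAC_OXONIUM = (
    ("HexNAc", "C8H13NO5"),
    ("HexNAc-H2O", "C8H11NO4"),
    ("HexNAc-2H2O", "C8H9NO3"),
    ("HexNAc-C2H4O2", "C6H9NO3"),
    ("HexNAc-CH6O3", "C7H7NO2"),
    ("HexNAc-C2H8O4", "C6H7NO2"),
)
_NEUAC_OXONIUM = (
    ("NeuAc", "C11H17NO8"),
    ("NeuAc-H2O", "C11H15NO7"),
)


def _kind_tables(kind: str):
    if kind == "mono":
        return RESIDUE_MONO, WATER_MONO
    if kind == "avg":
        return RESIDUE_AVG, WATER_AVG
    raise ValidationError(f"kind must be 'mono' or 'avg', got {kind!r}")


def peptide_mass(p: PeptideSequence | str, kind: str = "mono") -> float:
    """Neutral peptide mass: sum of residue masses plus one water."""
    residues = p.residues if isinstance(p, PeptideSequence) else str(PeptideSequence(p))
    table, water = _kind_tables(kind)
    return sum(table[aa] for aa in residues) + water


def glycopeptide_mass(
    e: GlycopeptideEpitope, alphabet: GlycanAlphabet, kind: str = "mono"
) -> float:
    """Neutral glycopeptide mass: peptide mass plus glycan residue masses.

    Glycan residue masses are dehydrated (glycosidic-bond) masses, so
    attachment is purely additive; an UNOCCUPIED state adds nothing.
    """
    total = peptide_mass(e.peptide, kind)
    for name in e.annotations.values():
        state = alphabet.state_of(name)
        total += alphabet.residue_mass(state, kind)
    return total


def mz(mass_da: float, z: int) -> float:
    """m/z of the z-fold protonated species, (M + z*m_H+)/z."""
    if z < 1:
        raise ValidationError(f"charge must be >= 1, got {z}")
    return (mass_da + z * PROTON) / z


def fragment_ions(
    e: GlycopeptideEpitope,
    alphabet: GlycanAlphabet,
    series: tuple[str, ...] = ("b", "y", "oxonium"),
) -> list[tuple[str, float]]:
    """Singly protonated CID fragment m/z values.

    b_i / y_i backbone ions are emitted in a glycan-lost variant
    (label ``b3``) and, when the fragment spans >= 1 annotated residue,
    a glycan-retained variant labelled with the retained glycan names
    (``b3+GalNAc``).  Oxonium ions are emitted once per glycan moiety
    type present (HexNAc-containing states yield the 204.087 series;
    NeuAc-containing states add the 292.103 series and the intact
    glyco-oxonium of the full state).
    """
    bad = set(series) - {"b", "y", "oxonium"}
    if bad:
        raise ValidationError(f"unknown fragment series {sorted(bad)}")
    residues = e.peptide.residues
    n = len(residues)
    prefix = [0.0]
    for aa in residues:
        prefix.append(prefix[-1] + RESIDUE_MONO[aa])

    def glycan_masses(positions) -> tuple[float, list[str]]:
        total, names = 0.0, []
        for pos in sorted(positions):
            name = e.annotations[pos]
            total += alphabet.residue_mass(alphabet.state_of(name), "mono")
            names.append(name)
        return total, names

    out: list[tuple[str, float]] = []
    if "b" in series:
        for i in range(1, n):
            bare = prefix[i] + PROTON
            out.append((f"b{i}", bare))
            span = [p for p in e.annotations if p <= i]
            if span:
                gmass, gnames = glycan_masses(span)
                out.append((f"b{i}+" + "+".join(gnames), bare + gmass))
    if "y" in series:
        for i in range(1, n):
            bare = prefix[n] - prefix[n - i] + WATER_MONO + PROTON
            out.append((f"y{i}", bare))
            span = [p for p in e.annotations if p > n - i]
            if span:
                gmass, gnames = glycan_masses(span)
                out.append((f"y{i}+" + "+".join(gnames), bare + gmass))
    if "oxonium" in series:
        state_names = set(e.annotations.values())
        has_hexnac = any("GalNAc" in s for s in state_names)
        has_neuac = any("NeuAc" in s for s in state_names)
        if has_hexnac:
            for label, formula in _HEXNAC_OXONIUM:
                out.append(
                    (f"oxonium:{label}",
                     _pmass.calculate_mass(formula=formula) + PROTON)
                )
        if has_neuac:
            for label, formula in _NEUAC_OXONIUM:
                out.append(
                    (f"oxonium:{label}",
                     _pmass.calculate_mass(formula=formula) + PROTON)
                )
            for s in sorted(state_names):
                if "NeuAc" in s:
                    state = alphabet.state_of(s)
                    out.append(
                        (f"oxonium:{s}",
                         alphabet.residue_mass(state, "mono") + PROTON)
                    )
    return out
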