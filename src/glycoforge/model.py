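"""Domain types for mucin glycopeptides.

A tandem-repeat mucin protein is modelled as flanks plus a repeat unit
times a copy number.  O-glycosylation states at Ser/Thr sites are drawn
from a :class:`GlycanAlphabet`: an ordered list of states whose digit 0 is
always UNOCCUPIED, so a per-site state vector is literally a base-k
number.  Glycan residue masses are computed from elemental composition
(never hard-coded decimals) via pyteomics.

All user-facing coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

from .errors import AlphabetLookupError, ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Name of alphabet state 0 (no glycan attached).
UNOCCUPIED = "UNOCCUPIED"


def _validate_residues(residues: str, label: str = "sequence") -> None:
    for i, ch in enumerate(residues, start=1):
        if ch not in AMINO_ACIDS:
            raise ValidationError(
                f"{label}: invalid amino-acid code {ch!r} at position {i}"
            )


@dataclass(frozen=True)
class PeptideSequence:
    """A validated one-letter amino-acid sequence with a free-text id."""

    residues: str
    id: str = ""

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValidationError("peptide sequence must have length >= 1")
        _validate_residues(self.residues, label=self.id or "sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, idx):
        return self.residues[idx]


@dataclass(frozen=True)
class TandemRepeatProtein:
    """A protein written as ``prefix + unit * copies + suffix``.

    Flanks are plain (possibly empty) residue strings; the repeat unit is
    a :class:`PeptideSequence`.  ``copies`` is the tandem-repeat copy
    number (MUC1 carries 25-125 copies of its 20-mer; small numbers are
    used throughout for library design).
    """

    unit: PeptideSequence
    copies: int
    n_prefix: str = ""
    c_suffix: str = ""
    id: str = ""

    def __post_init__(self):
        if self.copies < 1:
            raise ValidationError(f"copies must be >= 1, got {self.copies}")
        _validate_residues(self.n_prefix, label="n_prefix")
        _validate_residues(self.c_suffix, label="c_suffix")

    @property
    def sequence(self) -> str:
        return self.n_prefix + self.unit.residues * self.copies + self.c_suffix

    def full_sequence(self) -> PeptideSequence:
        return PeptideSequence(self.sequence, id=self.id or "tandem_repeat")

    def __len__(self) -> int:
        return len(self.sequence)

    def unit_start(self, copy_index: int) -> int:
        """1-based start position of repeat copy ``copy_index`` (1-based)."""
        if not 1 <= copy_index <= self.copies:
            raise ValidationError(
                f"copy_index must be in 1..{self.copies}, got {copy_index}"
            )
        return len(self.n_prefix) + (copy_index - 1) * len(self.unit) + 1

    @classmethod
    def from_sequence(
        cls, sequence: str, unit: PeptideSequence, copies: int, id: str = ""
    ) -> "TandemRepeatProtein":
        """Re-parse a plain sequence given the known unit and copy number."""
        if copies < 1:
            raise ValidationError(f"copies must be >= 1, got {copies}")
        block = unit.residues * copies
        pos = sequence.find(block)
        if pos < 0:
            raise ValidationError(
                f"sequence does not contain {copies} tandem copies of unit "
                f"{unit.residues!r}"
            )
        return cls(
            unit=unit,
            copies=copies,
            n_prefix=sequence[:pos],
            c_suffix=sequence[pos + len(block):],
            id=id,
        )


def make_tandem_repeat(
    unit: PeptideSequence | str,
    copies: int,
    prefix: str = "",
    suffix: str = "",
    id: str = "",
) -> TandemRepeatProtein:
    """Build a :class:`TandemRepeatProtein`; convenience over the constructor."""
    if isinstance(unit, str):
        unit = PeptideSequence(unit, id="unit")
    return TandemRepeatProtein(
        unit=unit, copies=copies, n_prefix=prefix, c_suffix=suffix, id=id
    )


@dataclass(frozen=True)
class GlycoSite:
    """A single O-glycosylation site: a Ser or Thr at a 1-based position."""

    position: int
    residue: str

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"site position must be >= 1, got {self.position}")
        if self.residue not in ("S", "T"):
            raise ValidationError(
                f"O-glycosylation site must be S or T, got {self.residue!r}"
            )


def _composition_mass(formula: str, average: bool = False) -> float:
    """Mass of a formula; '+'-joined parts are summed (e.g. disaccharides)."""
    comp = _pmass.Composition()
    for part in formula.split("+"):
        part = part.strip()
        if part:
            comp += _pmass.Composition(formula=part)
    return _pmass.calculate_mass(composition=comp, average=average)


@dataclass(frozen=True)
class Glycan:
    """A named glycan state: the mass it adds to a peptide on attachment.

    ``residue_mass_*`` is the residue (dehydrated) mass, i.e. the mass
    increment of the glycopeptide over the naked peptide — water is
    already accounted for.  If ``composition`` is given, masses are
    derived from it; multiple moieties may be joined with '+'
    (e.g. sialyl-Tn is "C8H13NO5+C11H17NO8").
    """

    name: str
    composition: str | None = None
    residue_mass_mono: float = field(default=0.0)
    residue_mass_avg: float = field(default=0.0)

    def __post_init__(self):
        if not self.name or self.name == UNOCCUPIED:
            raise ValidationError("glycan needs a non-empty name != UNOCCUPIED")
        if self.composition is not None:
            object.__setattr__(
                self, "residue_mass_mono", _composition_mass(self.composition)
            )
            object.__setattr__(
                self,
                "residue_mass_avg",
                _composition_mass(self.composition, average=True),
            )
        if self.residue_mass_mono <= 0:
            raise ValidationError(
                f"glycan {self.name!r}: residue mass must be positive "
                "(give a composition or explicit masses)"
            )
        if self.residue_mass_avg < self.residue_mass_mono - 1.0:
            raise ValidationError(
                f"glycan {self.name!r}: average mass implausibly below monoisotopic"
            )


# Built-in glycan states. Tn = single alpha-GalNAc; sialyl-Tn = the
# NeuAc(alpha2-6)GalNAc disaccharide treated as ONE state per site;
# Ac3GalNAc = tri-O-acetylated synthetic precursor (3 x C2H2O over GalNAc).
GALNAC = Glycan("GalNAc", composition="C8H13NO5")
NEUAC_GALNAC = Glycan("NeuAc-GalNAc", composition="C8H13NO5+C11H17NO8")
AC3GALNAC = Glycan("Ac3GalNAc", composition="C8H13NO5+C2H2O+C2H2O+C2H2O")

BUILTIN_GLYCANS = {g.name: g for g in (GALNAC, NEUAC_GALNAC, AC3GALNAC)}


@dataclass(frozen=True)
class GlycanAlphabet:
    """Ordered per-site glycan states; digit order is the enumeration order.

    State 0 is always UNOCCUPIED and is implicit: ``glycans`` holds
    states 1..k-1.  The binary (Tn) alphabet is ``[UNOCCUPIED, GalNAc]``;
    the ternary (Tn / sialyl-Tn) alphabet appends NeuAc-GalNAc.
    """

    glycans: tuple[Glycan, ...]
    name: str = ""

    def __post_init__(self):
        if len(self.glycans) < 1:
            raise ValidationError("alphabet needs at least one glycan state (k >= 2)")
        names = [g.name for g in self.glycans]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate glycan names in alphabet: {names}")

    @property
    def k(self) -> int:
        """Number of states per site, UNOCCUPIED included."""
        return len(self.glycans) + 1

    def state_name(self, state: int) -> str:
        if state == 0:
            return UNOCCUPIED
        return self.glycan(state).name

    def glycan(self, state: int) -> Glycan:
        if not 1 <= state <= len(self.glycans):
            raise AlphabetLookupError(
                f"state {state} out of range 1..{len(self.glycans)}"
            )
        return self.glycans[state - 1]

    def state_of(self, name: str) -> int:
        if name == UNOCCUPIED:
            return 0
        for i, g in enumerate(self.glycans, start=1):
            if g.name == name:
                return i
        raise AlphabetLookupError(f"unknown glycan name {name!r} in alphabet")

    def __contains__(self, name: str) -> bool:
        try:
            self.state_of(name)
            return True
        except AlphabetLookupError:
            return False

    def residue_mass(self, state: int, kind: str = "mono") -> float:
        if state == 0:
            return 0.0
        g = self.glycan(state)
        return g.residue_mass_mono if kind == "mono" else g.residue_mass_avg

    # -- serialization: small key/value text, one state per line ---------
    def to_text(self) -> str:
        lines = [f"# glycan alphabet: {self.name or 'unnamed'}",
                 "# state 0 (UNOCCUPIED) is implicit; order = digit order"]
        for g in self.glycans:
            if g.composition:
                lines.append(f"{g.name}\t{g.composition}")
            else:
                lines.append(f"{g.name}\tmono={g.residue_mass_mono}"
                             f",avg={g.residue_mass_avg}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, name: str = "") -> "GlycanAlphabet":
        glycans = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            if len(parts) != 2:
                raise ValidationError(
                    f"alphabet line {lineno}: expected 'name<TAB>composition', "
                    f"got {raw!r}"
                )
            gname, spec = parts[0].strip(), parts[1].strip()
            if spec.startswith("mono="):
                kv = dict(item.split("=", 1) for item in spec.split(","))
                glycans.append(
                    Glycan(gname,
                           residue_mass_mono=float(kv["mono"]),
                           residue_mass_avg=float(kv.get("avg", kv["mono"])))
                )
            else:
                glycans.append(Glycan(gname, composition=spec))
        return cls(glycans=tuple(glycans), name=name)


#: Binary paper-style alphabet: a site is naked or carries one GalNAc (Tn).
TN_ALPHABET = GlycanAlphabet(glycans=(GALNAC,), name="tn")
#: Ternary alphabet: naked, Tn, or sialyl-Tn.
TN_STN_ALPHABET = GlycanAlphabet(glycans=(GALNAC, NEUAC_GALNAC), name="tn-stn")

BUILTIN_ALPHABETS = {"tn": TN_ALPHABET, "tn-stn": TN_STN_ALPHABET}


@dataclass(frozen=True)
class Glycoform:
    """One assignment of a glycan state (integer digit) to each glycosite.

    The all-zero vector is the unmodified peptide; enumerated sets
    exclude it (counts are k^n - 1).
    """

    sites: tuple[GlycoSite, ...]
    states: tuple[int, ...]

    def __post_init__(self):
        if len(self.sites) != len(self.states):
            raise ValidationError(
                f"{len(self.sites)} sites but {len(self.states)} states"
            )
        if any(s < 0 for s in self.states):
            raise ValidationError("glycan states must be non-negative")

    @property
    def occupancy(self) -> int:
        """Number of occupied (nonzero-state) sites."""
        return sum(1 for s in self.states if s != 0)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def occupied(self) -> list[tuple[GlycoSite, int]]:
        return [(site, st) for site, st in zip(self.sites, self.states) if st != 0]

    def with_states(self, states) -> "Glycoform":
        return replace(self, states=tuple(int(s) for s in states))
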