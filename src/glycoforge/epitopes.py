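"""Candidate glycopeptide epitopes: annotation syntax, windows, dedup.

An annotated epitope is written with the glycan state name in
parentheses immediately after the modified residue, e.g.
``RPAPGS(GalNAc)TAPPAHG`` (GalNAc on the Thr at position 7).  Candidate
epitopes for antibody work are fixed-length peptide windows cut around
occupied glycosites of a tandem-repeat protein; repeat periodicity makes
many windows identical across copies, so libraries are deduplicated on
the rendered string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

from .errors import EpitopeSyntaxError, ValidationError
from .model import (
    GlycanAlphabet,
    GlycoSite,
    Glycoform,
    PeptideSequence,
    TandemRepeatProtein,
)

WINDOW_MODES = ("centered", "tiled")


@dataclass(frozen=True)
class GlycopeptideEpitope:
    """A peptide window plus per-position glycan annotations.

    ``annotations`` maps 1-based positions *within the window* to glycan
    state names; ``window_origin`` is the 1-based position of the window
    start within the parent protein (1 for standalone peptides).
    """

    peptide: PeptideSequence
    annotations: dict[int, str] = field(default_factory=dict)
    window_origin: int = 1

    def __post_init__(self):
        for pos, name in self.annotations.items():
            if not 1 <= pos <= len(self.peptide):
                raise ValidationError(
                    f"annotation position {pos} outside peptide of length "
                    f"{len(self.peptide)}"
                )
            if self.peptide[pos - 1] not in ("S", "T"):
                raise ValidationError(
                    f"annotation {name!r} at position {pos} sits on "
                    f"{self.peptide[pos - 1]!r}; O-glycans attach to S or T only"
                )
        if self.window_origin < 1:
            raise ValidationError("window_origin is 1-based and must be >= 1")

    @property
    def occupancy(self) -> int:
        return len(self.annotations)

    def render(self) -> str:
        return render_epitope(self)

    def __eq__(self, other):
        if not isinstance(other, GlycopeptideEpitope):
            return NotImplemented
        return (
            self.peptide.residues == other.peptide.residues
            and self.annotations == other.annotations
            and self.window_origin == other.window_origin
        )

    def __hash__(self):
        return hash(
            (self.peptide.residues, tuple(sorted(self.annotations.items())),
             self.window_origin)
        )


def render_epitope(e: GlycopeptideEpitope) -> str:
    """One-letter string with ``(StateName)`` right after each modified residue."""
    out = []
    for i, ch in enumerate(e.peptide.residues, start=1):
        out.append(ch)
        if i in e.annotations:
            out.append(f"({e.annotations[i]})")
    return "".join(out)


def parse_epitope(
    s: str, alphabet: GlycanAlphabet, window_origin: int = 1, id: str = ""
) -> GlycopeptideEpitope:
    """Inverse of :func:`render_epitope`; validates names against ``alphabet``.

    Raises :class:`EpitopeSyntaxError` on malformed parentheses, a
    lookup error on unknown glycan names, and a validation error when an
    annotation follows a residue other than S/T.
    """
    residues: list[str] = []
    annotations: dict[int, str] = {}
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            end = s.find(")", i + 1)
            if end < 0:
                raise EpitopeSyntaxError(f"unbalanced '(' at offset {i} in {s!r}")
            name = s[i + 1:end]
            if not residues:
                raise EpitopeSyntaxError(
                    f"annotation {name!r} precedes any residue in {s!r}"
                )
            pos = len(residues)
            if pos in annotations:
                raise EpitopeSyntaxError(
                    f"residue at position {pos} annotated twice in {s!r}"
                )
            # membership check raises AlphabetLookupError with the name
            alphabet.state_of(name)
            annotations[pos] = name
            i = end + 1
        elif ch == ")":
            raise EpitopeSyntaxError(f"unbalanced ')' at offset {i} in {s!r}")
        else:
            residues.append(ch)
            i += 1
    return GlycopeptideEpitope(
        peptide=PeptideSequence("".join(residues), id=id),
        annotations=annotations,
        window_origin=window_origin,
    )


def glycoform_epitope(
    seq: PeptideSequence, glycoform: Glycoform, alphabet: GlycanAlphabet
) -> GlycopeptideEpitope:
    """Annotate a whole peptide with one glycoform's occupied states."""
    annotations = {
        site.position: alphabet.state_name(state)
        for site, state in glycoform.occupied()
    }
    return GlycopeptideEpitope(peptide=seq, annotations=annotations)


def expand_to_protein(
    protein: TandemRepeatProtein, unit_glycoform: Glycoform
) -> Glycoform:
    """Lift a repeat-unit glycoform to full-protein coordinates, all copies.

    The same per-unit modification pattern is applied to every tandem
    copy — the homogeneous-glycoform assumption under which a repeat
    protein displays one pattern periodically.
    """
    full = protein.full_sequence()
    sites, states = [], []
    for copy_index in range(1, protein.copies + 1):
        offset = protein.unit_start(copy_index) - 1
        for site, state in zip(unit_glycoform.sites, unit_glycoform.states):
            pos = site.position + offset
            if full.residues[pos - 1] != site.residue:
                raise ValidationError(
                    f"unit site {site.position}{site.residue} does not match "
                    f"protein residue at {pos}"
                )
            sites.append(GlycoSite(position=pos, residue=site.residue))
            states.append(state)
    return Glycoform(sites=tuple(sites), states=tuple(states))


def extract_windows(
    protein: TandemRepeatProtein,
    glycoform: Glycoform,
    alphabet: GlycanAlphabet,
    window_len: int = 13,
    mode: str = "centered",
) -> list[GlycopeptideEpitope]:
    """Fixed-length candidate windows around occupied sites.

    ``glycoform`` uses full-protein coordinates (see
    :func:`expand_to_protein` to lift unit-level glycoforms).

    centered
        one window per occupied site, the site as close to position
        ceil(window_len/2) as the protein termini allow (windows are
        clipped, never dropped);
    tiled
        every length-``window_len`` window containing >= 1 occupied site.

    Each window is annotated with *all* occupied sites it covers and
    carries its 1-based origin in the protein.
    """
    if mode not in WINDOW_MODES:
        raise ValidationError(f"mode must be one of {WINDOW_MODES}, got {mode!r}")
    full = protein.full_sequence()
    n = len(full)
    if not 5 <= window_len <= n:
        raise ValidationError(
            f"window_len must be in 5..{n} (protein length), got {window_len}"
        )

    occupied = glycoform.occupied()
    by_pos = {site.position: alphabet.state_name(state)
              for site, state in occupied}

    def window_at(start: int) -> GlycopeptideEpitope:
        sub = full.residues[start - 1:start - 1 + window_len]
        annotations = {
            p - start + 1: name
            for p, name in by_pos.items()
            if start <= p <= start + window_len - 1
        }
        return GlycopeptideEpitope(
            peptide=PeptideSequence(sub, id=f"{full.id}:{start}"),
            annotations=annotations,
            window_origin=start,
        )

    windows: list[GlycopeptideEpitope] = []
    if mode == "centered":
        center_offset = ceil(window_len / 2) - 1
        for site, _state in occupied:
            start = site.position - center_offset
            start = max(1, min(start, n - window_len + 1))
            windows.append(window_at(start))
    else:
        for start in range(1, n - window_len + 2):
            if any(start <= p <= start + window_len - 1 for p in by_pos):
                windows.append(window_at(start))
    return windows


def unique_epitopes(
    epitopes: list[GlycopeptideEpitope],
) -> list[GlycopeptideEpitope]:
    """Deduplicate on the rendered string, keeping first occurrence order.

    Origins are ignored: the same annotated window cut from different
    tandem copies is one library entry.
    """
    seen: set[str] = set()
    out = []
    for e in epitopes:
        key = render_epitope(e)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def build_library(
    protein: TandemRepeatProtein,
    alphabet: GlycanAlphabet,
    window_len: int = 13,
    mode: str = "centered",
    order: str = "occupancy",
) -> list[GlycopeptideEpitope]:
    """Enumerate unit glycoforms, cut windows, deduplicate: the full
    candidate-epitope library for a tandem-repeat protein."""
    from .enumeration import EnumerationSpec, enumerate_glycoforms, identify_glycosites

    sites = tuple(identify_glycosites(protein.unit))
    spec = EnumerationSpec(sites=sites, alphabet=alphabet, order=order)
    epitopes: list[GlycopeptideEpitope] = []
    for gf in enumerate_glycoforms(spec):
        lifted = expand_to_protein(protein, gf)
        epitopes.extend(
            extract_windows(protein, lifted, alphabet, window_len, mode)
        )
    return unique_epitopes(epitopes)
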