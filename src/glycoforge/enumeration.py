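"""Exhaustive enumeration of O-glycoforms over Ser/Thr sites.

A peptide with n glycosites and a k-state glycan alphabet (state 0 =
unoccupied) admits k^n per-site state vectors; excluding the all-zero
(unmodified) vector leaves k^n - 1 glycoforms.  For the MUC1 20-mer
repeat (n = 5) this gives 31 Tn glycoforms with the binary alphabet and
242 with the ternary Tn / sialyl-Tn alphabet.  The enumerated set can be
exported as a sites x glycoforms occupancy matrix of integer states.

Two orderings are supported:

``occupancy``
    occupancy (number of glycans) ascending, ties broken
    lexicographically on the state vector with site 1 most significant —
    the natural order when glycoforms are grouped by glycan count;
``counter``
    plain base-k counting order (the state vector read as a base-k
    integer, site 1 most significant), i.e. the literal digit-counting
    construction.

Counts and set-identity are independent of the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .errors import SizeGuardError, ValidationError
from .model import GlycanAlphabet, GlycoSite, Glycoform, PeptideSequence

#: Default combinatorial guard: refuse > 5^20 state vectors by accident.
MAX_SITES = 20
MAX_STATES = 5

ORDERS = ("occupancy", "counter")


def identify_glycosites(seq: PeptideSequence | str) -> list[GlycoSite]:
    """Every Ser/Thr position of ``seq``, ascending, 1-based.

    This is the candidate O-glycosylation site scan used for mucin
    repeats: all five sites of the MUC1 20-mer are Ser/Thr and all are
    treated as modifiable.
    """
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq
    return [
        GlycoSite(position=i, residue=ch)
        for i, ch in enumerate(residues, start=1)
        if ch in ("S", "T")
    ]


@dataclass(frozen=True)
class EnumerationSpec:
    """What to enumerate: the site list, the alphabet, and the ordering."""

    sites: tuple[GlycoSite, ...]
    alphabet: GlycanAlphabet
    order: str = "occupancy"
    max_sites: int = MAX_SITES
    max_states: int = MAX_STATES

    def __post_init__(self):
        if self.order not in ORDERS:
            raise ValidationError(f"order must be one of {ORDERS}, got {self.order!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total(self) -> int:
        """Number of enumerated glycoforms, k^n - 1."""
        return self.alphabet.k ** self.n_sites - 1


def enumerate_glycoforms(
    spec: EnumerationSpec, include_unmodified: bool = False
) -> list[Glycoform]:
    """All k^n - 1 glycoforms over ``spec.sites`` in the requested order.

    The all-zero (unmodified) vector is excluded unless
    ``include_unmodified`` is set, in which case it is prepended (it is
    the naked-peptide control, not part of the enumerated modified set).
    """
    n, k = spec.n_sites, spec.alphabet.k
    if n < 1:
        raise ValidationError("enumeration needs at least one glycosite")
    if n > spec.max_sites or k > spec.max_states:
        raise SizeGuardError(
            f"enumeration over n={n} sites, k={k} states exceeds the size guard "
            f"(max_sites={spec.max_sites}, max_states={spec.max_states}); "
            "raise the bounds explicitly if this is intentional"
        )

    # Base-k digit vectors for 1..k^n-1, site 1 most significant.
    def digits(value: int) -> tuple[int, ...]:
        out = []
        for _ in range(n):
            value, d = divmod(value, k)
            out.append(d)
        return tuple(reversed(out))

    vectors = [digits(v) for v in range(1, k**n)]
    if spec.order == "occupancy":
        vectors.sort(key=lambda st: (sum(1 for d in st if d), st))

    forms = [Glycoform(sites=spec.sites, states=st) for st in vectors]
    if include_unmodified:
        forms.insert(0, Glycoform(sites=spec.sites, states=(0,) * n))
    return forms


def count_isomers(n_sites: int, occupancy: int, k: int = 2) -> int:
    """Positional/state isomers with exactly ``occupancy`` occupied sites.

    C(n, m) * (k-1)^m: choose which m sites are occupied, then one of
    the k-1 glycan states per occupied site.  For the binary alphabet
    this is the plain binomial coefficient (5, 10, 10, 5, 1 for the
    5-site repeat).
    """
    if not 0 <= occupancy <= n_sites:
        raise ValidationError(
            f"occupancy must be in 0..{n_sites}, got {occupancy}"
        )
    if k < 2:
        raise ValidationError(f"alphabet must have k >= 2 states, got {k}")
    return comb(n_sites, occupancy) * (k - 1) ** occupancy


@dataclass(frozen=True)
class OccupancyMatrix:
    """Sites x glycoforms integer-state matrix (the 5 x 31 construction)."""

    site_positions: tuple[int, ...]
    matrix: np.ndarray = field(repr=False)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_glycoforms(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=[f"site_{p}" for p in self.site_positions],
            columns=[f"gf{j + 1}" for j in range(self.n_glycoforms)],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="site")

    def to_long_frame(self, alphabet: GlycanAlphabet) -> pd.DataFrame:
        """Long format: one row per (glycoform, site) with the state name."""
        rows = [
            {
                "glycoform_id": f"gf{j + 1}",
                "site_position": p,
                "state": int(self.matrix[i, j]),
                "state_name": alphabet.state_name(int(self.matrix[i, j])),
            }
            for j in range(self.n_glycoforms)
            for i, p in enumerate(self.site_positions)
        ]
        return pd.DataFrame(rows)


def occupancy_matrix(glycoforms: list[Glycoform]) -> OccupancyMatrix:
    """Stack glycoform state vectors as matrix columns.

    All glycoforms must share one site list; columns therefore align
    site-by-site and (for an enumerated set) are pairwise distinct with
    no all-zero column.
    """
    if not glycoforms:
        raise ValidationError("occupancy matrix needs at least one glycoform")
    sites = glycoforms[0].sites
    for g in glycoforms[1:]:
        if g.sites != sites:
            raise ValidationError(
                "glycoforms have heterogeneous site lists; cannot stack"
            )
    mat = np.array([g.states for g in glycoforms], dtype=int).T
    return OccupancyMatrix(
        site_positions=tuple(s.position for s in sites), matrix=mat
    )
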