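"""File I/O: FASTA, CSV/TSV tables, packaged reference data.

CSV dialect: comma-separated, UTF-8, mandatory header row, '.' decimal
separator; matrices use TSV.  FASTA handling goes through Biopython.

Packaged data (under ``glycoforge/data``): the two MUC1 repeat-unit
phases, the three benchmark annotated epitope strings, an IHC staining
table, an SPR kinetic-constant table, and the built-in glycan alphabet
definitions.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .epitopes import GlycopeptideEpitope, render_epitope
from .errors import ValidationError
from .model import (
    BUILTIN_ALPHABETS,
    GlycanAlphabet,
    PeptideSequence,
)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path) -> list[PeptideSequence]:
    """Protein FASTA -> validated peptide sequences, order preserved.

    Record ids are the description up to the first whitespace; sequences
    are uppercased and wrapped lines joined.  An empty file and
    non-amino-acid characters are explicit errors naming the record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"FASTA file {path} contains no records")
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        try:
            out.append(PeptideSequence(residues, id=rec.id))
        except ValidationError as exc:
            raise ValidationError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(seqs: list[PeptideSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id or f"seq{i + 1}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Epitope libraries
# --------------------------------------------------------------------------

def library_frame(epitopes: list[GlycopeptideEpitope]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(epitopes, start=1):
        rows.append(
            {
                "epitope_id": f"ep{i}",
                "rendered": render_epitope(e),
                "peptide": e.peptide.residues,
                "origin": e.window_origin,
                "occupancy": e.occupancy,
                "annotations": ";".join(
                    f"{pos}:{name}" for pos, name in sorted(e.annotations.items())
                ),
                "glycans": ";".join(
                    name for _, name in sorted(e.annotations.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "epitope_id", "rendered", "peptide", "origin",
            "occupancy", "annotations", "glycans",
        ],
    )


def write_library_csv(epitopes: list[GlycopeptideEpitope], path) -> None:
    library_frame(epitopes).to_csv(path, index=False)


def write_library_fasta(epitopes: list[GlycopeptideEpitope], path) -> None:
    """Bare peptides as sequences; the rendered string in the description."""
    records = [
        SeqRecord(
            Seq(e.peptide.residues),
            id=f"ep{i + 1}",
            description=render_epitope(e),
        )
        for i, e in enumerate(epitopes)
    ]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Binding-data tables
# --------------------------------------------------------------------------

def read_elisa_csv(path) -> pd.DataFrame:
    """ELISA points with columns concentration_ng_ml, response."""
    df = pd.read_csv(path)
    required = {"concentration_ng_ml", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ELISA CSV {path} missing columns {sorted(missing)}")
    return df


def read_spr_constants_csv(path) -> pd.DataFrame:
    """SPR constants with columns analyte, ka_per_M_s, kd_per_s."""
    df = pd.read_csv(path)
    required = {"analyte", "ka_per_M_s", "kd_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"SPR CSV {path} missing columns {sorted(missing)}")
    return df


def read_sensorgrams_csv(path):
    """Long-format sensorgram table -> list of Sensorgram.

    Columns: time_s, response_RU, concentration_M, t_assoc_s; one group
    of rows per concentration.
    """
    from .binding import Sensorgram

    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "concentration_M", "t_assoc_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"sensorgram CSV {path} missing columns {sorted(missing)}"
        )
    out = []
    for conc, grp in df.groupby("concentration_M", sort=True):
        out.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                concentration=float(conc),
                t_assoc=float(grp["t_assoc_s"].iloc[0]),
            )
        )
    return out


def write_sensorgrams_csv(sensorgrams, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": sg.time,
                "response_RU": sg.response,
                "concentration_M": sg.concentration,
                "t_assoc_s": sg.t_assoc,
            }
        )
        for sg in sensorgrams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_json(fit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


# --------------------------------------------------------------------------
# Packaged reference data
# --------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("glycoforge.data").joinpath(name).read_text()


def load_alphabet(spec: str) -> GlycanAlphabet:
    """Resolve ``builtin:<name>`` or a path to an alphabet definition file."""
    if spec.startswith("builtin:"):
        name = spec.split(":", 1)[1]
        if name not in BUILTIN_ALPHABETS:
            raise ValidationError(
                f"unknown builtin alphabet {name!r}; "
                f"have {sorted(BUILTIN_ALPHABETS)}"
            )
        return BUILTIN_ALPHABETS[name]
    path = Path(spec)
    if not path.exists():
        raise ValidationError(f"alphabet file {spec} does not exist")
    return GlycanAlphabet.from_text(path.read_text(), name=path.stem)


def load_repeat_units() -> list[PeptideSequence]:
    """The two 20-mer MUC1 tandem-repeat phases."""
    import io as _io

    records = list(SeqIO.parse(_io.StringIO(_data_text("muc1_repeats.fasta")), "fasta"))
    return [PeptideSequence(str(r.seq).upper(), id=r.id) for r in records]


def load_benchmark_epitope_strings() -> list[str]:
    """The three annotated benchmark epitope strings."""
    return [
        line.strip()
        for line in _data_text("benchmark_epitopes.txt").splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_ihc_table() -> pd.DataFrame:
    """Breast-cancer IHC staining table (10 patients, +/- calls)."""
    import io as _io

    return pd.read_csv(_io.StringIO(_data_text("ihc_staining.tsv")), sep="\t",
                       dtype=str)


def load_spr_table() -> pd.DataFrame:
    """SPR kinetic constants for two antibodies x three (glyco)peptides.

    The chi2_RU2 column is the instrument-software fit residual and is
    carried as metadata only.
    """
    import io as _io

    return pd.read_csv(_io.StringIO(_data_text("spr_constants.csv")))
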