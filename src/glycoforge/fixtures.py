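"""Synthetic fixture generation: mucin-like proteins and binding data.

The generator emulates the shape of a mucin tandem-repeat experiment
without any real accession: a repeat unit of configurable length with a
chosen number of non-adjacent Ser/Thr glycosites (MUC1-like defaults:
20-mer unit, 5 sites, 3 copies), ELISA dose-response points drawn from
known 4PL parameters, and sensorgrams drawn from known 1:1 Langmuir
constants.  Ground-truth parameters are written alongside, so recovery
pipelines can be tested end to end.  Identical spec + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .binding import simulate_elisa_curve, simulate_sensorgram
from .errors import ValidationError
from .io import write_fasta, write_sensorgrams_csv
from .model import PeptideSequence, make_tandem_repeat

# Residues used to fill non-glycosite positions (no S/T, so the site
# count is exactly as requested).
_FILLER = "ADEFGHIKLMNPQRVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture set.

    Binding defaults are in the range of moderate-affinity IgG /
    glycopeptide interactions: KD = kd/ka = 500 nM, ELISA EC50 about
    10 ng/ml with a unit hill slope.
    """

    seed: int
    unit_length: int = 20
    n_sites: int = 5
    copies: int = 3
    # ELISA ground truth
    elisa_bottom: float = 0.05
    elisa_top: float = 1.8
    elisa_ec50_ng_ml: float = 10.0
    elisa_hill: float = 1.0
    elisa_noise_sd: float = 0.05
    elisa_concentrations: tuple[float, ...] = (
        0.41, 1.23, 3.7, 11.1, 33.3, 100.0, 300.0, 900.0,
    )
    # SPR ground truth (KD = 500 nM)
    spr_ka: float = 5e4
    spr_kd: float = 0.025
    spr_rmax: float = 100.0
    spr_t_assoc: float = 120.0
    spr_t_total: float = 320.0
    spr_noise_sd: float = 2.0
    spr_concentrations_nM: tuple[float, ...] = (50.0, 500.0, 5000.0)


def random_repeat_unit(
    unit_length: int, n_sites: int, rng: np.random.Generator
) -> PeptideSequence:
    """A unit with exactly ``n_sites`` S/T at random non-adjacent positions."""
    if n_sites < 0 or unit_length < 1:
        raise ValidationError("need unit_length >= 1 and n_sites >= 0")
    # n non-adjacent positions in L slots exist iff n <= ceil(L/2)
    if n_sites > (unit_length + 1) // 2:
        raise ValidationError(
            f"cannot place {n_sites} non-adjacent glycosites in a "
            f"{unit_length}-mer unit"
        )
    # sample gaps construction: choose n of (L - n + 1) then spread
    base = rng.choice(unit_length - n_sites + 1, size=n_sites, replace=False)
    base.sort()
    positions = {int(p + i) for i, p in enumerate(base)}
    residues = [
        ("ST"[rng.integers(2)] if i in positions
         else _FILLER[rng.integers(len(_FILLER))])
        for i in range(unit_length)
    ]
    return PeptideSequence("".join(residues), id="synthetic_unit")


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> dict:
    """Build the full synthetic fixture set; optionally write it to disk.

    Returns a dict with the protein, the ELISA curve, the sensorgrams,
    and the ground-truth parameter dict.  When ``out_dir`` is given,
    writes protein.fasta, elisa.csv, sensorgrams.csv and truth.json.
    """
    rng = np.random.default_rng(spec.seed)
    unit = random_repeat_unit(spec.unit_length, spec.n_sites, rng)
    protein = make_tandem_repeat(unit, copies=spec.copies, id="synthetic_mucin")

    # child seeds keep each stream reproducible yet independent
    elisa_seed = int(rng.integers(2**31 - 1))
    elisa = simulate_elisa_curve(
        spec.elisa_concentrations,
        bottom=spec.elisa_bottom, top=spec.elisa_top,
        ec50=spec.elisa_ec50_ng_ml, hill=spec.elisa_hill,
        noise_sd=spec.elisa_noise_sd, seed=elisa_seed, label="synthetic",
    )
    sensorgrams = []
    for conc_nM in spec.spr_concentrations_nM:
        sg_seed = int(rng.integers(2**31 - 1))
        sensorgrams.append(
            simulate_sensorgram(
                spec.spr_ka, spec.spr_kd, conc_nM * 1e-9, spec.spr_rmax,
                t_assoc=spec.spr_t_assoc, t_total=spec.spr_t_total,
                noise_sd=spec.spr_noise_sd, seed=sg_seed,
            )
        )
    truth = {
        "unit": unit.residues,
        "copies": spec.copies,
        "elisa": {
            "bottom": spec.elisa_bottom, "top": spec.elisa_top,
            "ec50_ng_ml": spec.elisa_ec50_ng_ml, "hill": spec.elisa_hill,
            "noise_sd": spec.elisa_noise_sd,
        },
        "spr": {
            "ka_per_M_s": spec.spr_ka, "kd_per_s": spec.spr_kd,
            "rmax_RU": spec.spr_rmax,
            "KD_nM": spec.spr_kd / spec.spr_ka * 1e9,
            "noise_sd_RU": spec.spr_noise_sd,
        },
        "seed": spec.seed,
    }
    result = {
        "protein": protein,
        "elisa": elisa,
        "sensorgrams": sensorgrams,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([protein.full_sequence()], out / "protein.fasta")
        import pandas as pd

        pd.DataFrame(
            {"concentration_ng_ml": elisa.concentration,
             "response": elisa.response}
        ).to_csv(out / "elisa.csv", index=False)
        write_sensorgrams_csv(sensorgrams, out / "sensorgrams.csv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return result
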