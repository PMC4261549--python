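"""Synthetic benchmark generator.

Emits complete datasets — sequences, per-residue binding labels,
pseudo-PSSM profiles, pseudo secondary-structure probabilities — plus
writers that reproduce the exact on-disk dialects the readers in
:mod:`vitabind.io` consume, so the whole pipeline can be exercised with
no external tools or downloads.

The generative model plants three recoverable signals:

* a per-letter binding propensity bias (some amino acids are more likely
  to be labeled binding, mimicking the residue preferences of real
  vitamin-binding sites),
* a window-context effect coupling a residue's label probability to the
  bias composition of its +-8 neighbourhood,
* a label-linked shift of the residue's own profile row along a fixed
  random direction (the analogue of binding sites being evolutionarily
  conserved and hence profile-visible).

An optional ``leakage_effect`` plants within-sequence homology, in two
parts: every profile row of a sequence receives one shared random
offset (a sequence fingerprint), and the sequence's binding residues
are additionally shifted along a random *sequence-specific* direction
(binding sites of one protein share their own conservation signature).
Residue-level cross-validation sees other residues of the same sequence
during training and can learn both; sequence-level cross-validation
holds out whole sequences, for which the sequence-specific signature is
fresh noise.

Pseudo-PSSM values are integers in [-10, 10], the scale of real
PSI-BLAST log-odds; secondary-structure rows are Dirichlet draws tilted
toward coil for binding residues and quantized to the 3 decimals the
upstream predictor prints.  All randomness flows from one seed through
``numpy.random.SeedSequence`` spawning, so sub-generators (sequences,
labels, profiles, SS) are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .io import (
    PSSM_RESIDUE_ORDER,
    STANDARD_AA,
    ProfileMatrix,
    ProteinRecord,
    SSProbMatrix,
)

#: Default per-letter bias multipliers for P(binding | letter).  Polar,
#: charged and small residues are favoured, bulky hydrophobics avoided —
#: a caricature of the residue preferences seen at cofactor sites.
DEFAULT_PROPENSITY_BIAS: Dict[str, float] = {
    "H": 3.0, "C": 2.5, "D": 2.2, "E": 2.0, "K": 1.8, "R": 1.8,
    "S": 1.6, "T": 1.5, "N": 1.3, "Q": 1.2, "G": 1.2, "Y": 1.0,
    "W": 0.9, "M": 0.8, "P": 0.8, "A": 0.7, "F": 0.6, "V": 0.6,
    "L": 0.5, "I": 0.5,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    The defaults emulate the composition of the vitamin-binding
    benchmarks this pipeline targets: ~1:20 positive:negative residue
    imbalance, sequences long enough to hold a full 17-residue window,
    and a planted propensity/profile signal strong enough for a
    sequence-level cross-validated model to beat chance clearly.
    """

    n_sequences: int = 24
    length_range: Tuple[int, int] = (30, 60)
    positive_fraction: float = 0.05
    propensity_bias: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPENSITY_BIAS)
    )
    context_effect: float = 0.5
    leakage_effect: float = 0.0
    rate_heterogeneity: float = 0.5  # s.d. of the per-sequence log rate multiplier
    profile_signal: float = 4.0   # norm of the label-linked profile shift
    profile_noise: float = 1.5    # s.d. of the integer-rounded profile noise
    ss_signal: float = 1.0        # coil tilt of the Dirichlet for positives
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must lie in (0,1)")
        if self.length_range[0] < 17:
            raise ValueError("minimum length must be >= 17 so a full window exists")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max) with min <= max")
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")


@dataclass
class SyntheticDataset:
    records: List[ProteinRecord]
    profiles: Dict[str, ProfileMatrix]
    ss: Dict[str, SSProbMatrix]
    config: GeneratorConfig


def _letter_signature() -> np.ndarray:
    """Fixed 20x20 base profile: strong own-column log-odds, mild background."""
    sig = np.full((20, 20), -2.0)
    np.fill_diagonal(sig, 4.0)
    return sig


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a complete labeled dataset from the generative model."""
    ss_root = np.random.SeedSequence(config.seed)
    ss_seq, ss_lab, ss_prof, ss_ssmat = ss_root.spawn(4)
    rng_seq = np.random.default_rng(ss_seq)
    rng_lab = np.random.default_rng(ss_lab)
    rng_prof = np.random.default_rng(ss_prof)
    rng_ss = np.random.default_rng(ss_ssmat)

    letters = np.array(list(STANDARD_AA))
    log_bias = np.log(
        np.array([config.propensity_bias.get(a, 1.0) for a in STANDARD_AA])
    )
    letter_pos = {a: i for i, a in enumerate(STANDARD_AA)}

    lengths = rng_seq.integers(
        config.length_range[0], config.length_range[1] + 1, size=config.n_sequences
    )
    sequences = [
        "".join(rng_seq.choice(letters, size=L)) for L in lengths
    ]

    # per-residue label rates, calibrated so the dataset mean equals the
    # target positive fraction
    raw_rates: List[np.ndarray] = []
    for seq in sequences:
        lb = np.array([log_bias[letter_pos[a]] for a in seq])
        ctx = np.array(
            [lb[max(0, i - 8) : i + 9].mean() for i in range(len(seq))]
        )
        # per-sequence rate multiplier: proteins differ in how densely
        # their binding pocket samples the chain
        m = np.exp(config.rate_heterogeneity * rng_lab.standard_normal())
        raw_rates.append(m * np.exp(lb + config.context_effect * (ctx - lb.mean())))
    all_raw = np.concatenate(raw_rates)
    scale = config.positive_fraction / all_raw.mean()
    # rates are probabilities: the far tail of the per-sequence multiplier
    # saturates at 1, but a *systematically* unreachable target fraction is
    # a configuration error
    clipped = float(((all_raw * scale) > 1.0).mean())
    if clipped > 0.01:
        raise ValueError(
            "infeasible positive_fraction for the given biases: "
            f"{clipped:.1%} of residue rates would exceed 1"
        )

    sig = _letter_signature()
    # one fixed, learnable shift direction shared by all sequences
    d = rng_prof.standard_normal(20)
    d /= np.linalg.norm(d)
    shift = config.profile_signal * d

    records: List[ProteinRecord] = []
    profiles: Dict[str, ProfileMatrix] = {}
    ssmats: Dict[str, SSProbMatrix] = {}
    for idx, seq in enumerate(sequences):
        rid = f"syn{idx:04d}"
        rates = np.minimum(raw_rates[idx] * scale, 1.0)
        labs = (rng_lab.random(len(seq)) < rates).astype(np.int8)

        base = np.stack([sig[letter_pos[a]] for a in seq])
        if config.leakage_effect > 0:
            # sequence fingerprint + sequence-specific binding signature
            offset = rng_prof.standard_normal(20) * config.leakage_effect
            d_seq = rng_prof.standard_normal(20)
            d_seq *= config.leakage_effect / np.linalg.norm(d_seq)
        else:
            offset = np.zeros(20)
            d_seq = np.zeros(20)
        noise = rng_prof.standard_normal((len(seq), 20)) * config.profile_noise
        values = (
            base
            + labs[:, None] * (shift + d_seq)[None, :]
            + offset[None, :]
            + noise
        )
        values = np.clip(np.rint(values), -10, 10)
        profiles[rid] = ProfileMatrix(
            values=values, normalized=False, residues=seq
        )

        alpha_neg = np.array([2.0, 2.0, 2.0])
        alpha_pos = alpha_neg + np.array([2.0 * config.ss_signal, 0.0, 0.0])
        probs = np.stack(
            [
                rng_ss.dirichlet(alpha_pos if l else alpha_neg)
                for l in labs
            ]
        )
        # quantize to the 3 decimals the on-disk dialect carries
        probs = np.vectorize(lambda p: float(f"{p:.3f}"))(probs)
        ssmats[rid] = SSProbMatrix(values=np.clip(probs, 0.0, 1.0))

        records.append(ProteinRecord(id=rid, sequence=seq, labels=labs))

    return SyntheticDataset(records=records, profiles=profiles, ss=ssmats, config=config)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A signal-free configuration: flat biases, no context or profile shift."""
    base = GeneratorConfig(
        propensity_bias={a: 1.0 for a in STANDARD_AA},
        context_effect=0.0,
        rate_heterogeneity=0.0,
        profile_signal=0.0,
        ss_signal=0.0,
        seed=seed,
    )
    return replace(base, **overrides)


def _write_pssm(path: Path, record: ProteinRecord, profile: ProfileMatrix) -> None:
    cols = " ".join(f"{a:>3}" for a in PSSM_RESIDUE_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write(f"          {cols} {cols}\n")
        for i, (letter, row) in enumerate(zip(record.sequence, profile.values), start=1):
            logodds = " ".join(f"{int(v):3d}" for v in row)
            percents = " ".join(f"{0:3d}" for _ in row)
            fh.write(f"{i:5d} {letter}  {logodds}  {percents}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3177\n")


SS_STATE = {0: "C", 1: "H", 2: "E"}


def _write_ss2(path: Path, record: ProteinRecord, ssmat: SSProbMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (PSIPRED V4.0)\n")
        fh.write("\n")
        for i, (letter, row) in enumerate(zip(record.sequence, ssmat.values), start=1):
            state = SS_STATE[int(np.argmax(row))]
            fh.write(
                f"{i:4d} {letter} {state}  {row[0]:6.3f} {row[1]:6.3f} {row[2]:6.3f}\n"
            )


def write_fixture_tree(dataset: SyntheticDataset, directory) -> Dict[str, Path]:
    """Write FASTA + per-sequence .pssm/.ss2 + labels under ``directory``.

    The readers in :mod:`vitabind.io` round-trip every file exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pssm_dir = directory / "pssm"
    ss_dir = directory / "ss2"
    pssm_dir.mkdir(exist_ok=True)
    ss_dir.mkdir(exist_ok=True)

    fasta = directory / "sequences.fasta"
    labels = directory / "labels.txt"
    with open(fasta, "w") as ffh, open(labels, "w") as lfh:
        for rec in dataset.records:
            ffh.write(f">{rec.id}\n{rec.sequence}\n")
            lfh.write(f"{rec.id}\t{''.join(str(int(l)) for l in rec.labels)}\n")
            _write_pssm(pssm_dir / f"{rec.id}.pssm", rec, dataset.profiles[rec.id])
            _write_ss2(ss_dir / f"{rec.id}.ss2", rec, dataset.ss[rec.id])
    return {
        "fasta": fasta,
        "labels": labels,
        "pssm_dir": pssm_dir,
        "ss2_dir": ss_dir,
    }
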