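"""Per-residue feature construction.

Each residue is described by three serially concatenated blocks extracted
with a sliding window of odd size W (default 17) centred on the residue:

* ``pssm``  — W x 20 logistic-normalized PSSM values (340-D at W=17),
* ``ss``    — W x 3 predicted secondary-structure probabilities (51-D),
* ``vbp``   — W x 1 amino-acid binding propensities (17-D),

for a total of 24*W = 408 dimensions at the default window.

Window rows falling outside the sequence are padded with the neutral
element of each block: 0.5 for the PSSM block (the logistic image of a
zero log-odds), 1/3 per state for the SS block, and the table's mean
propensity for the VBP block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import (
    STANDARD_AA,
    ProfileMatrix,
    ProteinRecord,
    SSProbMatrix,
)

DEFAULT_WINDOW = 17


def logistic_normalize(profile: ProfileMatrix) -> ProfileMatrix:
    """Map raw log-odds x to 1/(1+e^-x), element-wise."""
    if profile.normalized:
        raise ValueError("profile is already normalized")
    values = 1.0 / (1.0 + np.exp(-profile.values))
    return ProfileMatrix(
        values=values,
        normalized=True,
        residue_order=profile.residue_order,
        residues=profile.residues,
    )


@dataclass
class PropensityTable:
    """Per-amino-acid binding propensity estimated from labeled residues.

    The propensity of letter ``a`` is the fraction of training residues of
    type ``a`` that carry a positive (binding) label.  Letters never seen
    in training receive the mean propensity over observed letters, as do
    ambiguity codes at lookup time.  The table must only ever be built
    from training residues, never from a held-out fold.
    """

    values: Dict[str, float]
    vitamin_class: str = "generic"
    source_counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"propensity of {a!r} outside [0,1]: {v}")

    @property
    def mean_propensity(self) -> float:
        return float(np.mean(list(self.values.values())))

    def lookup(self, letter: str) -> float:
        return self.values.get(letter, self.mean_propensity)


def compute_binding_propensities(
    records: Sequence[ProteinRecord], vitamin_class: str = "generic"
) -> PropensityTable:
    """Estimate per-letter binding propensities from labeled records."""
    records = list(records)
    if not records:
        raise ValueError("cannot compute propensities from an empty record list")
    binding = {a: 0 for a in STANDARD_AA}
    total = {a: 0 for a in STANDARD_AA}
    for rec in records:
        if rec.labels is None:
            raise ValueError(f"record {rec.id!r} carries no labels")
        for letter, lab in zip(rec.sequence, rec.labels):
            if letter in total:
                total[letter] += 1
                binding[letter] += int(lab)
    observed = {a: binding[a] / total[a] for a in STANDARD_AA if total[a] > 0}
    if not observed:
        raise ValueError("no standard residues observed in training records")
    mean_obs = float(np.mean(list(observed.values())))
    values = {a: observed.get(a, mean_obs) for a in STANDARD_AA}
    counts = {a: (binding[a], total[a]) for a in STANDARD_AA}
    return PropensityTable(values=values, vitamin_class=vitamin_class, source_counts=counts)


def window_features(
    matrix: np.ndarray, position: int, W: int, pad_value: float
) -> np.ndarray:
    """Concatenate the W rows of ``matrix`` centred on ``position``.

    Out-of-range rows are replaced by a constant row of ``pad_value``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window size must be odd and positive, got {W}")
    L, K = matrix.shape
    if not (0 <= position < L):
        raise ValueError(f"position {position} outside [0,{L})")
    half = (W - 1) // 2
    out = np.full((W, K), pad_value, dtype=float)
    lo = max(0, position - half)
    hi = min(L, position + half + 1)
    out[lo - (position - half) : hi - (position - half)] = matrix[lo:hi]
    return out.ravel()


@dataclass
class FeatureMatrix:
    """M x D matrix of residue feature vectors with block provenance.

    ``block_spans`` maps block name -> (start, stop) column span;
    ``residue_index`` holds the (sequence id, 0-based position) of each row.
    """

    values: np.ndarray
    block_spans: Dict[str, Tuple[int, int]]
    residue_index: List[Tuple[str, int]]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.residue_index):
            raise ValueError("row count does not match residue index")
        stops = sorted(self.block_spans.values())
        edges = [0] + [s[1] for s in stops]
        if any(stops[i][0] != edges[i] for i in range(len(stops))) or edges[-1] != self.values.shape[1]:
            raise ValueError("block spans must partition the column range")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("label vector length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_spans[name]
        return self.values[:, lo:hi]


def build_feature_matrix(
    records: Sequence[ProteinRecord],
    profiles: Mapping[str, ProfileMatrix],
    ss: Mapping[str, SSProbMatrix],
    propensities: PropensityTable,
    W: int = DEFAULT_WINDOW,
) -> FeatureMatrix:
    """Build the concatenated PSSM | SS | VBP feature matrix.

    One row per residue over all records, in input order.  Raw profiles
    are logistic-normalized on the fly; already-normalized ones are used
    as given.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    if W % 2 == 0:
        raise ValueError(f"window size must be odd, got {W}")

    rows: List[np.ndarray] = []
    index: List[Tuple[str, int]] = []
    labels: List[int] = []
    have_labels = all(rec.labels is not None for rec in records)
    mean_prop = propensities.mean_propensity

    for rec in records:
        if rec.id not in profiles:
            raise ValueError(f"missing profile for record {rec.id!r}")
        if rec.id not in ss:
            raise ValueError(f"missing secondary-structure matrix for record {rec.id!r}")
        prof = profiles[rec.id]
        if prof.residues is not None and prof.residues != rec.sequence:
            # profiles are derived artifacts; the FASTA sequence is trusted
            warnings.warn(
                f"record {rec.id!r}: profile residue letters differ from the "
                "FASTA sequence; using the FASTA sequence"
            )
        if not prof.normalized:
            prof = logistic_normalize(prof)
        ssm = ss[rec.id]
        if len(prof) != len(rec) or len(ssm) != len(rec):
            raise ValueError(f"record {rec.id!r}: profile/SS length mismatch")
        vbp_track = np.array(
            [[propensities.lookup(a)] for a in rec.sequence], dtype=float
        )
        for pos in range(len(rec)):
            row = np.concatenate(
                [
                    window_features(prof.values, pos, W, pad_value=0.5),
                    window_features(ssm.values, pos, W, pad_value=1.0 / 3.0),
                    window_features(vbp_track, pos, W, pad_value=mean_prop),
                ]
            )
            rows.append(row)
            index.append((rec.id, pos))
            if have_labels:
                labels.append(int(rec.labels[pos]))

    spans = {
        "pssm": (0, 20 * W),
        "ss": (20 * W, 23 * W),
        "vbp": (23 * W, 24 * W),
    }
    return FeatureMatrix(
        values=np.vstack(rows),
        block_spans=spans,
        residue_index=index,
        labels=np.array(labels, dtype=np.int8) if have_labels else None,
    )
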