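"""Sequence-level disorder indicators: the charge-hydropathy plane.

Intrinsically disordered proteins combine a high net charge with low mean
hydropathy; ordered proteins cluster on the opposite side of a straight
boundary in the (<H>, <R>) plane.  This module computes both coordinates
from a protein sequence and classifies the point.

Conventions (matching the common web implementations of the plot):

* Kyte-Doolittle hydropathies rescaled to [0, 1] via (KD + 4.5) / 9;
* hydropathy smoothed over fully interior sliding windows (default 5);
* K and R count +1, D and E count -1; H, C, Y and the termini are treated
  as neutral at pH 7; net charge is the absolute per-residue excess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from . import config

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
_POSITIVE = set("KR")
_NEGATIVE = set("DE")


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence over the 20 canonical one-letter codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("empty input")
        bad = set(self.residues) - CANONICAL
        if bad:
            raise ValueError(
                f"non-canonical residues {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CHResult:
    """A point on the charge-hydropathy plane with its classification."""

    mean_hydropathy: float
    mean_net_charge: float
    boundary_charge: float
    label: str  # "ordered" | "disordered"

    def to_dict(self) -> dict:
        return {
            "mean_hydropathy": self.mean_hydropathy,
            "mean_net_charge": self.mean_net_charge,
            "boundary_charge": self.boundary_charge,
            "label": self.label,
        }


def clean_sequence(seq_id: str, residues: str, strict: bool = True) -> ProteinSequence:
    """Build a :class:`ProteinSequence`, upper-casing the input.

    In strict mode any non-canonical letter raises; in lenient mode such
    letters are skipped with a warning (useful for sequences containing X
    or alignment gaps).
    """
    residues = residues.upper().replace("*", "").replace("-", "")
    if not strict:
        kept = [r for r in residues if r in CANONICAL]
        if len(kept) != len(residues):
            warnings.warn(
                f"{len(residues) - len(kept)} non-canonical residues skipped "
                f"in {seq_id!r}",
                stacklevel=2,
            )
        residues = "".join(kept)
    return ProteinSequence(id=seq_id, residues=residues)


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinSequence]:
    """Read one or more sequences from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [clean_sequence(rec.id, str(rec.seq), strict=strict) for rec in records]


def mean_net_charge(seq: ProteinSequence) -> float:
    """Absolute net charge per residue: |#(K,R) - #(D,E)| / length."""
    n_pos = sum(1 for r in seq.residues if r in _POSITIVE)
    n_neg = sum(1 for r in seq.residues if r in _NEGATIVE)
    return abs(n_pos - n_neg) / len(seq)


def rescaled_kd(residue: str) -> float:
    """Kyte-Doolittle hydropathy rescaled from [-4.5, 4.5] to [0, 1]."""
    return (KYTE_DOOLITTLE[residue] + 4.5) / 9.0


def mean_hydropathy(seq: ProteinSequence, window: int = 5) -> float:
    """Mean rescaled Kyte-Doolittle hydropathy over interior sliding windows.

    Per-residue values are averaged within each window of `window`
    consecutive residues (no padding: a length-N sequence yields N-window+1
    windows), then the window means are averaged.  window=1 reduces to the
    plain per-residue mean.
    """
    n = len(seq)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    values = np.array([rescaled_kd(r) for r in seq.residues])
    if window == 1:
        return float(values.mean())
    kernel = np.full(window, 1.0 / window)
    window_means = np.convolve(values, kernel, mode="valid")
    return float(window_means.mean())


def classify_charge_hydropathy(
    h: float,
    r: float,
    slope: float = config.CH_SLOPE,
    intercept: float = config.CH_INTERCEPT,
) -> CHResult:
    """Classify a (<H>, <R>) point against the order/disorder boundary.

    The boundary is <R> = slope * <H> + intercept; points with net charge
    strictly above the line are disordered.  A point exactly on the line is
    called "ordered" (the conservative call).
    """
    if not (0.0 <= h <= 1.0) or not (0.0 <= r <= 1.0):
        raise ValueError(f"(h={h}, r={r}) outside the unit square")
    boundary = slope * h + intercept
    label = "disordered" if r > boundary else "ordered"
    return CHResult(
        mean_hydropathy=h, mean_net_charge=r, boundary_charge=boundary, label=label
    )


def profile_sequence(seq: ProteinSequence, window: int = 5) -> CHResult:
    """Compute both plane coordinates for a sequence and classify them."""
    return classify_charge_hydropathy(
        mean_hydropathy(seq, window=window), mean_net_charge(seq)
    )
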