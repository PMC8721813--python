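"""Position count/frequency matrices and composition-adjusted bias logos.

Given a set of fixed-length sequences (TSD 8-mers, or the 28-base
TSD+flank windows cut from tagmentation reads) this module builds the
position weight matrix and scores each position against the genome
composition q(b) with the Kullback-Leibler divergence

    D_i = sum_b p_i(b) * log2(p_i(b) / q(b))        [bits, 0*log0 := 0]

and per-base signed contributions

    h_i(b) = p_i(b) * log2(p_i(b) / q(b))

where positive h means the base is over-represented at that position
relative to the genome and negative means under-represented.  These are
the numeric tables behind composition-adjusted (Blogo-style) sequence
logos; rendering is left to plotting layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BASES, BASE_INDEX, Background, DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Per-position base counts C[i][b] over n_sequences windows."""

    counts: np.ndarray  # (L, 4) int
    n_sequences: int
    n_excluded: int = 0  # windows dropped for containing N

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass
class FrequencyMatrix:
    """Per-position base frequencies p_i(b); rows sum to 1."""

    p: np.ndarray  # (L, 4) float
    pseudocount: float = 0.0

    @property
    def length(self) -> int:
        return self.p.shape[0]


@dataclass
class LogoProfile:
    """Composition-adjusted logo: per-position bits and per-base contributions."""

    kl_bits: np.ndarray  # (L,)
    base_bits: np.ndarray  # (L, 4) signed h_i(b)
    freqs: FrequencyMatrix
    background: Background

    @property
    def length(self) -> int:
        return self.kl_bits.shape[0]


def build_count_matrix(seqs: list[str], length: int) -> CountMatrix:
    """Count bases at the first ``length`` positions of each sequence.

    Sequences shorter than ``length`` raise; windows containing N within
    the first ``length`` bases are excluded (and counted).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    counts = np.zeros((length, 4), dtype=np.int64)
    n_used = 0
    n_excluded = 0
    for seq in seqs:
        if len(seq) < length:
            raise ValueError(f"sequence shorter than matrix length {length}: {seq!r}")
        window = seq[:length]
        if "N" in window:
            n_excluded += 1
            continue
        for i, b in enumerate(window):
            counts[i, BASE_INDEX[b]] += 1
        n_used += 1
    if n_excluded:
        logger.info("excluded %d N-containing windows from count matrix", n_excluded)
    if n_used == 0:
        raise DegenerateInputError("no usable sequences after N exclusion")
    return CountMatrix(counts=counts, n_sequences=n_used, n_excluded=n_excluded)


def to_frequency(counts: CountMatrix, pseudocount: float | None = None) -> FrequencyMatrix:
    """Normalize counts to frequencies with an optional symmetric pseudocount.

    With ``pseudocount=None`` a small-sample default applies: 0 when
    n_sequences >= 50, else 0.5.
    """
    if pseudocount is None:
        pseudocount = 0.0 if counts.n_sequences >= 50 else 0.5
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = counts.n_sequences + 4.0 * pseudocount
    p = (counts.counts + pseudocount) / denom
    return FrequencyMatrix(p=p, pseudocount=pseudocount)


def _check_background(p: np.ndarray, q: np.ndarray) -> None:
    if ((q == 0) & (p > 0)).any():
        raise DegenerateInputError(
            "background frequency 0 where observed frequency > 0; "
            "apply a pseudocount or use a positive background"
        )


def relative_entropy(freqs: FrequencyMatrix, background: Background) -> np.ndarray:
    """Per-position KL divergence D_i in bits (0*log0 treated as 0)."""
    p = freqs.p
    q = background.array
    _check_background(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / q), 0.0)
    return terms.sum(axis=1)


def base_bias_bits(freqs: FrequencyMatrix, background: Background) -> np.ndarray:
    """Signed per-base contributions h_i(b) = p_i(b) * log2(p_i(b)/q(b)).

    Positive values mark over-represented bases, negative under-represented
    (note h -> 0 as p -> 0: a fully absent base contributes nothing).
    """
    p = freqs.p
    q = background.array
    _check_background(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / q), 0.0)
    return h


def make_profile(freqs: FrequencyMatrix, background: Background) -> LogoProfile:
    return LogoProfile(
        kl_bits=relative_entropy(freqs, background),
        base_bits=base_bias_bits(freqs, background),
        freqs=freqs,
        background=background,
    )


def region_labels(length: int, tsd_len: int = 8) -> list[str]:
    """Row labels: positions 1..tsd_len are 'TSD', the rest '+1', '+2', ..."""
    labels = []
    for i in range(length):
        labels.append("TSD" if i < tsd_len else f"+{i - tsd_len + 1}")
    return labels


def write_logo_data(profile: LogoProfile, path: str | Path, tsd_len: int = 8) -> None:
    """Serialize the logo as a TSV table, one row per position.

    Columns: position (1-based), region, kl_bits, h_A..h_T, p_A..p_T.
    Header line starts with '#'.
    """
    cols = ["position", "region", "kl_bits"]
    cols += [f"h_{b}" for b in BASES] + [f"p_{b}" for b in BASES]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        labels = region_labels(profile.length, tsd_len)
        for i in range(profile.length):
            row = [str(i + 1), labels[i], repr(float(profile.kl_bits[i]))]
            row += [repr(float(x)) for x in profile.base_bits[i]]
            row += [repr(float(x)) for x in profile.freqs.p[i]]
            fh.write("\t".join(row) + "\n")


def read_logo_data(path: str | Path) -> pd.DataFrame:
    """Read a logo TSV written by :func:`write_logo_data`."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df
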