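"""Estimate the TBP-promoter equilibrium dissociation constant (KD).

The estimator is a calibrated surrogate of the three-step model of TBP
binding to a core promoter:

(i)   TBP slides along the double helix, held by nonspecific affinity
      (KD ~ 1e-5 M);
(ii)  TBP stops at a TATA-like site recognised through a position
      weight matrix;
(iii) the complex is stabilised by bending of the DNA axis.

Steps (i) and (ii) fix two affinity anchors: a promoter with no
recognisable site binds TBP at the nonspecific ceiling, a promoter with
a perfect consensus site binds at the specific floor (KD ~ 1e-9 M).
Step (iii)'s stabilisation is absorbed into a linear interpolation in
ln KD between the anchors, driven by the best window's normalised
recognition score:

    ln KD = ln KD_ns + s* (ln KD_sp - ln KD_ns),   s* in [0, 1]

where s* is the maximum, over all windows on both strands of the 90 bp
promoter, of the log-odds score divided by the consensus score (clipped
below at zero, i.e. background-level windows cannot beat nonspecific
sliding).  The promoter KD is set by the single best window — the
maximum-occupancy site at which TBP stops — not by a sum over windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

from .promoter_io import PROMOTER_LENGTH

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PathLike = Union[str, Path]


class MatrixFormatError(ValueError):
    """The matrix source is not a valid 4 x width numeric table."""


class Strand(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class TataMatrix:
    """Position probability matrix for the TATA-box recognition step.

    ``probs`` has shape (width, 4) in base order A, C, G, T; each row
    sums to one and is strictly positive (a pseudocount is applied when
    loading count matrices).  ``background`` is the genomic base
    composition the log-odds score is referred to (uniform by default).
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise MatrixFormatError("probs must be a (width, 4) array")
        if probs.shape[0] < 6:
            raise MatrixFormatError("matrix width must be >= 6")
        if not np.all(probs > 0):
            raise MatrixFormatError("all probabilities must be strictly positive")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise MatrixFormatError("each position's probabilities must sum to 1")
        if bg.shape != (4,) or not np.all(bg > 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise MatrixFormatError("background must be 4 positive probs summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) array of ln(p / background)."""
        return np.log(self.probs / self.background)

    @property
    def consensus(self) -> str:
        """Modal base at each position (ties broken in A<C<G<T order)."""
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    @property
    def max_score(self) -> float:
        """Log-odds score of the consensus window."""
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class CalibrationAnchors:
    """The two printed affinity anchors of the binding model, in mol/L."""

    kd_nonspecific: float = 1e-5
    kd_specific: float = 1e-9

    def __post_init__(self):
        if not 0 < self.kd_specific < self.kd_nonspecific:
            raise ValueError("require 0 < kd_specific < kd_nonspecific")


@dataclass(frozen=True)
class AffinityEstimate:
    """Estimated KD for one promoter, with the winning window."""

    kd: float  # mol/L
    ln_kd: float
    best_start: int  # 1-based, forward-strand coordinates of window left end
    best_strand: Strand
    best_score: float  # normalised recognition score in [0, 1]

    @property
    def kd_nM(self) -> float:
        return self.kd * 1e9


def load_matrix(
    matrix_source: PathLike,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
) -> TataMatrix:
    """Load a 4-row (A, C, G, T) whitespace-separated matrix file.

    Rows may be counts or probabilities; each column is normalised to a
    probability vector after adding ``pseudocount``.  ``#`` starts a
    comment.  A column of all zeros therefore becomes uniform.
    """
    rows: dict[str, list[float]] = {}
    text = Path(matrix_source).read_text() if not hasattr(matrix_source, "read") else matrix_source.read()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(":", " ").replace("|", " ").split()
        label = parts[0].upper()
        if label not in _BASE_INDEX:
            raise MatrixFormatError(f"unexpected row label {parts[0]!r}")
        if label in rows:
            raise MatrixFormatError(f"duplicate row for base {label}")
        try:
            rows[label] = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"non-numeric cell in row {label}: {exc}") from None
    if set(rows) != set(BASES):
        raise MatrixFormatError(f"need rows A, C, G, T; got {sorted(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise MatrixFormatError(f"ragged rows, widths {sorted(widths)}")
    (width,) = widths
    if width < 6:
        raise MatrixFormatError(f"matrix width {width} < 6")
    counts = np.array([rows[b] for b in BASES], dtype=float).T  # (width, 4)
    if np.any(counts < 0):
        raise MatrixFormatError("negative entries are not allowed")
    counts = counts + pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return TataMatrix(probs=probs, background=bg, pseudocount=pseudocount)


def default_matrix() -> TataMatrix:
    """The package's 15-column TATAWAWR position frequency matrix."""
    with resources.files("tatakd.data").joinpath("tata_pfm.txt").open() as fh:
        return load_matrix(fh)


def encode(sequence: str) -> np.ndarray:
    """Map an ACGT string to an int array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if np.any(out < 0):
        bad = sorted(set(sequence) - set(BASES))
        raise ValueError(f"sequence contains non-ACGT character(s) {bad}")
    return out


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement (involution on ACGT strings)."""
    if set(sequence) - set(BASES):
        bad = sorted(set(sequence) - set(BASES))
        raise ValueError(f"cannot complement non-DNA character(s) {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def log_odds_score(window: str, matrix: TataMatrix) -> float:
    """Sum over positions of ln(p_pos(base) / background(base))."""
    idx = encode(window)
    if idx.size != matrix.width:
        raise ValueError(f"window length {idx.size} != matrix width {matrix.width}")
    return float(matrix.log_odds[np.arange(matrix.width), idx].sum())


def normalized_site_score(window: str, matrix: TataMatrix) -> float:
    """Log-odds score relative to the consensus, clipped to [0, 1]."""
    s_max = matrix.max_score
    if s_max <= 0:
        raise ValueError("degenerate matrix: consensus score is not positive")
    return max(0.0, log_odds_score(window, matrix) / s_max)


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of an encoded sequence (vectorised)."""
    width = log_odds.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(encoded, width)
    return log_odds[np.arange(width), windows].sum(axis=1)


def scan_best_window(
    sequence: str, matrix: TataMatrix
) -> tuple[float, int, Strand]:
    """Best normalised score over all windows on both strands.

    Returns ``(score, start, strand)`` where ``start`` is the 1-based
    position of the window's left end in forward-strand coordinates.
    Ties are broken in favour of the forward strand, then the smaller
    start position.
    """
    s_max = matrix.max_score
    if s_max <= 0:
        raise ValueError("degenerate matrix: consensus score is not positive")
    n, width = len(sequence), matrix.width
    if n < width:
        raise ValueError(f"sequence length {n} < matrix width {width}")
    lo = matrix.log_odds
    fwd = _window_scores(encode(sequence), lo)
    rev = _window_scores(encode(reverse_complement(sequence)), lo)

    # forward strand wins ties; np.argmax takes the first (smallest start)
    j_fwd = int(np.argmax(fwd))
    best_score, start, strand = float(fwd[j_fwd]), j_fwd + 1, Strand.FORWARD
    # on the reverse complement, window j spans forward positions
    # (n - width - j + 1) .. (n - j); smaller forward start = larger j,
    # so scan reversed to prefer the smaller forward start on ties
    j_rev = rev.size - 1 - int(np.argmax(rev[::-1]))
    if float(rev[j_rev]) > best_score + 1e-12:
        best_score = float(rev[j_rev])
        start = n - width - j_rev + 1
        strand = Strand.REVERSE
    score = max(0.0, best_score / s_max)
    return min(1.0, score), start, strand


def estimate_kd(
    sequence: str,
    matrix: TataMatrix | None = None,
    anchors: CalibrationAnchors | None = None,
) -> AffinityEstimate:
    """Estimate KD of the TBP complex with one 90 bp promoter.

    Scans every window on both strands, takes the best normalised
    recognition score s*, and interpolates linearly in ln KD between
    the nonspecific ceiling (s* = 0) and the specific floor (s* = 1).
    """
    matrix = matrix if matrix is not None else default_matrix()
    anchors = anchors if anchors is not None else CalibrationAnchors()
    if len(sequence) != PROMOTER_LENGTH:
        raise ValueError(
            f"promoter length {len(sequence)} != {PROMOTER_LENGTH}"
        )
    score, start, strand = scan_best_window(sequence, matrix)
    ln_ns = math.log(anchors.kd_nonspecific)
    ln_sp = math.log(anchors.kd_specific)
    # endpoints return the anchors exactly (no exp/log round-trip error)
    if score == 0.0:
        kd = anchors.kd_nonspecific
    elif score == 1.0:
        kd = anchors.kd_specific
    else:
        kd = math.exp(ln_ns + score * (ln_sp - ln_ns))
    return AffinityEstimate(
        kd=kd,
        ln_kd=math.log(kd),
        best_start=start,
        best_strand=strand,
        best_score=score,
    )
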