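"""PWM-based scanning of promoter variants for gained/lost TF binding sites.

Scoring follows the JASPAR-style relative-score convention: each matrix
column is normalized to base frequencies, regularized toward a uniform
background (p = (f + a*bg) / (1 + a) with a = 0.1, bg = 0.25), and a window
scores sum_i log2(p_i(base_i) / 0.25). The relative score rescales the raw
log-odds between the matrix's minimum and maximum attainable scores, so it
lies in [0, 1] and is invariant to rescaling the count matrix. A site "hit"
is a window at or above the threshold (default 0.75); a variant gains a site
when an alt-allele window crosses the threshold that its ref counterpart did
not reach, and loses one in the converse case. Both strands are scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import PwmError

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: regularization weight toward the uniform background
PSEUDOCOUNT_ALPHA = 0.1
BACKGROUND = 0.25


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """A position weight matrix over A/C/G/T.

    ``matrix`` holds per-position counts (or probabilities; any positive
    scale — columns are normalized). Shape: (length, 4) in A, C, G, T order.
    """

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise PwmError(f"{self.name}: matrix must be (length, 4)")
        if (self.matrix < 0).any():
            raise PwmError(f"{self.name}: negative matrix entries")
        sums = self.matrix.sum(axis=1)
        if (sums <= 0).any():
            raise PwmError(f"{self.name}: empty matrix column")
        freqs = self.matrix / sums[:, None]
        self._probs = (freqs + PSEUDOCOUNT_ALPHA * BACKGROUND) / (
            1.0 + PSEUDOCOUNT_ALPHA
        )
        self._logodds = np.log2(self._probs / BACKGROUND)
        self._max = float(self._logodds.max(axis=1).sum())
        self._min = float(self._logodds.min(axis=1).sum())

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Pseudocount-regularized per-position probabilities (rows sum to 1)."""
        return self._probs.copy()

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self._probs.argmax(axis=1))

    def raw_score(self, window: str) -> float:
        """Sum of log2(p/background) over the window; requires A/C/G/T only."""
        if len(window) != self.length:
            raise PwmError(
                f"{self.name}: window length {len(window)} != {self.length}"
            )
        try:
            idx = [_BASE_INDEX[b] for b in window.upper()]
        except KeyError as exc:
            raise PwmError(
                f"{self.name}: ambiguous/invalid base {exc.args[0]!r}"
            ) from None
        return float(self._logodds[np.arange(self.length), idx].sum())

    def relative_score(self, window: str) -> float:
        """(raw - min) / (max - min), in [0, 1]."""
        span = self._max - self._min
        if span == 0:  # fully degenerate matrix
            return 1.0
        return (self.raw_score(window) - self._min) / span


def relative_score(seq_window: str, pwm: Pwm) -> float:
    """Module-level convenience wrapper around :meth:`Pwm.relative_score`."""
    return pwm.relative_score(seq_window)


def read_jaspar(path: str | Path) -> list[Pwm]:
    """Read JASPAR PFM flat files (">" headers, four count rows).

    Accepts both the bracketed 4-row layout (``A [ 1 2 3 ]``) and the plain
    4-row layout; parsing is delegated to Bio.motifs.
    """
    from Bio import motifs

    with open(path) as fh:
        text = fh.read()
    fmt = "jaspar" if "[" in text else "pfm-four-rows"
    import io

    parsed = motifs.parse(io.StringIO(text), fmt)
    out = []
    for m in parsed:
        counts = np.array(
            [[m.counts[b][i] for b in _BASES] for i in range(m.length)],
            dtype=float,
        )
        name = (
            f"{m.matrix_id} {m.name}".strip()
            if getattr(m, "matrix_id", None)
            else (m.name or "pwm")
        )
        out.append(Pwm(name=name, matrix=counts))
    if not out:
        raise PwmError(f"{path}: no matrices found")
    return out


@dataclass(frozen=True)
class SiteHit:
    """A scoring window: position offset in the supplied sequence, strand,
    raw log-odds score and min-max rescaled relative score."""

    pwm_name: str
    start: int  # 0-based offset of the window in the supplied sequence
    strand: str  # "+" or "-"
    raw_score: float
    relative: float


def _windows_overlapping(
    seq: str, pwm: Pwm, var_pos: int, full: bool
) -> Iterable[int]:
    if full:
        return range(0, len(seq) - pwm.length + 1)
    lo = max(0, var_pos - pwm.length + 1)
    hi = min(len(seq) - pwm.length, var_pos)
    return range(lo, hi + 1)


def _scan(
    seq: str, pwms: Sequence[Pwm], var_pos: int, full: bool
) -> dict[tuple[str, int, str], SiteHit]:
    hits: dict[tuple[str, int, str], SiteHit] = {}
    for pwm in pwms:
        for start in _windows_overlapping(seq, pwm, var_pos, full):
            window = seq[start : start + pwm.length]
            if set(window.upper()) - set(_BASES):
                continue  # skip windows with ambiguous bases
            for strand in "+-":
                w = window if strand == "+" else revcomp(window)
                raw = pwm.raw_score(w)
                hits[(pwm.name, start, strand)] = SiteHit(
                    pwm_name=pwm.name,
                    start=start,
                    strand=strand,
                    raw_score=raw,
                    relative=pwm.relative_score(w),
                )
    return hits


@dataclass
class ScanResult:
    gained: list[SiteHit]
    lost: list[SiteHit]


def scan_variant(
    ref_seq: str,
    alt_seq: str,
    pwms: Sequence[Pwm],
    threshold: float = 0.75,
    full: bool = False,
) -> ScanResult:
    """Gained and lost binding sites induced by a single-base substitution.

    ``ref_seq`` and ``alt_seq`` must be equal length and differ at exactly
    one position (SNV mode). Windows overlapping the variant are scored on
    both strands; gained = alt window >= threshold while the matching ref
    window < threshold; lost = the converse. Hits are sorted by relative
    score (descending), then window position, then strand. ``full=True``
    scans the entire sequence instead of variant-overlapping windows only.
    """
    ref_seq, alt_seq = ref_seq.upper(), alt_seq.upper()
    if len(ref_seq) != len(alt_seq):
        raise PwmError("ref and alt sequences must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
    if len(diffs) == 0:
        return ScanResult(gained=[], lost=[])
    if len(diffs) > 1:
        raise PwmError(
            f"sequences differ at {len(diffs)} positions; expected exactly 1"
        )
    var_pos = diffs[0]
    ref_hits = _scan(ref_seq, pwms, var_pos, full)
    alt_hits = _scan(alt_seq, pwms, var_pos, full)

    def sort_key(h: SiteHit):
        return (-h.relative, h.start, h.strand)

    gained = sorted(
        (
            h
            for k, h in alt_hits.items()
            if h.relative >= threshold
            and (k not in ref_hits or ref_hits[k].relative < threshold)
        ),
        key=sort_key,
    )
    lost = sorted(
        (
            h
            for k, h in ref_hits.items()
            if h.relative >= threshold
            and (k not in alt_hits or alt_hits[k].relative < threshold)
        ),
        key=sort_key,
    )
    return ScanResult(gained=gained, lost=lost)
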