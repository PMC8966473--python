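"""Window construction and eigenanalysis of allele-frequency-change matrices.

For each genomic window of ``n`` consecutive SNPs, the change in polarized
allele frequency between the source population and each of ``m`` derived
populations forms an m×n matrix X. After scaling each row (one derived
population's change vector) to unit Euclidean length, C = XXᵀ is the m×m
matrix of cosine similarities between change vectors. Its eigenvalues sum
to m; an excess of variance on the first eigenvector means the replicate
populations changed along a shared multivariate axis, and the signs of the
populations' loadings on that eigenvector distinguish parallel (all same
sign) from antiparallel (mixed sign) change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import AlleleFrequencyTable

logger = logging.getLogger(__name__)

SIGN_TOL = 1e-10  # loadings within ±SIGN_TOL of zero get an indeterminate sign

__all__ = [
    "Window",
    "DeltaAFWindow",
    "EigenResult",
    "DirectionCall",
    "DegenerateWindowError",
    "build_windows",
    "delta_matrix",
    "normalize_rows",
    "eigen_decompose",
    "classify_direction",
    "analyze_windows",
    "results_to_frame",
]


class DegenerateWindowError(ValueError):
    """A window whose change matrix cannot define directions (all-zero row)."""


@dataclass(frozen=True)
class Window:
    """A run of consecutive SNPs on one chromosome.

    ``start`` / ``stop`` are half-open row indices into the originating
    :class:`AlleleFrequencyTable`; ``start_bp`` / ``end_bp`` are the 1-based
    positions of the first and last SNP.
    """

    chrom: str
    start: int
    stop: int
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.stop - self.start

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


@dataclass
class DeltaAFWindow:
    """ΔAF matrix X (m populations × n SNPs) for one window."""

    window: Window
    X: np.ndarray
    populations: list[str]
    normalized: bool = False


@dataclass
class EigenResult:
    """Spectrum of C = XXᵀ for one window.

    ``eigenvalues`` are sorted descending; ``loadings[:, k]`` is the k-th
    eigenvector (orthonormal), sign-fixed so the first population's loading
    is non-negative.
    """

    window: Window
    eigenvalues: np.ndarray
    loadings: np.ndarray
    populations: list[str]

    @property
    def m(self) -> int:
        return len(self.eigenvalues)

    def statistic(self, eigenvector: int = 1) -> float:
        """λ₁ for the first eigenvector, cumulative Σλ for higher ones."""
        if not (1 <= eigenvector <= self.m):
            raise ValueError(f"eigenvector index must be in [1, {self.m}]")
        return float(self.eigenvalues[:eigenvector].sum())


@dataclass
class DirectionCall:
    """Per-population loading signs on one eigenvector, with a summary label."""

    signs: list[str]                 # '+', '-' or '0' per population
    label: str                       # 'parallel', 'antiparallel', 'indeterminate'
    partition: tuple[tuple[str, ...], tuple[str, ...]] | None
    populations: list[str]


def build_windows(freqs: AlleleFrequencyTable, snps_per_window: int = 200) -> list[Window]:
    """Tile each chromosome into consecutive windows of exactly n SNPs.

    A terminal remainder of fewer than ``snps_per_window`` SNPs is discarded
    so every window has the same dimension as the permutation null.
    """
    if snps_per_window < 2:
        raise ValueError("snps_per_window must be >= 2")
    windows: list[Window] = []
    offset = 0
    for chrom in pd.unique(freqs.chrom):
        n = int(np.sum(freqs.chrom == chrom))
        n_win = n // snps_per_window
        if n_win == 0:
            logger.warning("chromosome %s has %d SNPs (< %d): no windows", chrom, n, snps_per_window)
        for w in range(n_win):
            a = offset + w * snps_per_window
            b = a + snps_per_window
            windows.append(Window(chrom=str(chrom), start=a, stop=b,
                                  start_bp=int(freqs.pos[a]), end_bp=int(freqs.pos[b - 1])))
        offset += n
    return windows


def delta_matrix(freqs: AlleleFrequencyTable, window: Window,
                 derived: list[str] | None = None) -> DeltaAFWindow:
    """X[j, i] = freq of the polarized allele in derived pop j minus source, SNP i."""
    derived = list(derived) if derived is not None else freqs.derived
    src = freqs.source_freq[window.start:window.stop]
    X = np.empty((len(derived), window.n_snps), dtype=np.float64)
    for j, pop in enumerate(derived):
        X[j] = freqs.freq(pop)[window.start:window.stop] - src
    return DeltaAFWindow(window=window, X=X, populations=derived)


def normalize_rows(daf: DeltaAFWindow) -> DeltaAFWindow:
    """Scale every row of X to unit Euclidean length.

    Raises :class:`DegenerateWindowError` if a row is all zeros (a population
    with no allele-frequency change has no direction of change); callers
    exclude such windows from the eigenanalysis.
    """
    norms = np.linalg.norm(daf.X, axis=1)
    zero = norms == 0.0
    if np.any(zero):
        bad = [daf.populations[j] for j in np.flatnonzero(zero)]
        raise DegenerateWindowError(
            f"window {daf.window.label}: all-zero ΔAF row for population(s) {bad}")
    return DeltaAFWindow(window=daf.window, X=daf.X / norms[:, None],
                         populations=daf.populations, normalized=True)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the first (near-)nonzero loading is positive.

    The first population's loading governs the sign; if it is numerically
    zero the next population breaks the tie, keeping output deterministic.
    """
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        lead = np.flatnonzero(np.abs(col) > SIGN_TOL)
        if len(lead) and col[lead[0]] < 0:
            out[:, k] = -col
    return out


def eigen_decompose(daf: DeltaAFWindow) -> EigenResult:
    """Eigendecomposition of C = XXᵀ for a row-normalized window."""
    if not daf.normalized:
        daf = normalize_rows(daf)
    C = daf.X @ daf.X.T
    try:
        vals, vecs = np.linalg.eigh(C)
    except np.linalg.LinAlgError as e:  # pragma: no cover - eigh on m×m rarely fails
        raise RuntimeError(f"eigendecomposition failed for window {daf.window.label}") from e
    order = np.argsort(vals)[::-1]
    return EigenResult(window=daf.window, eigenvalues=vals[order],
                       loadings=_fix_signs(vecs[:, order]), populations=daf.populations)


def classify_direction(result: EigenResult, eigenvector: int = 1,
                       tol: float = SIGN_TOL) -> DirectionCall:
    """Parallel / antiparallel call from loading signs on one eigenvector."""
    if not (1 <= eigenvector <= result.m):
        raise ValueError(f"eigenvector index must be in [1, {result.m}]")
    load = result.loadings[:, eigenvector - 1]
    signs = ["0" if abs(v) <= tol else ("+" if v > 0 else "-") for v in load]
    if "0" in signs:
        return DirectionCall(signs=signs, label="indeterminate", partition=None,
                             populations=result.populations)
    if len(set(signs)) == 1:
        return DirectionCall(signs=signs, label="parallel", partition=None,
                             populations=result.populations)
    plus = tuple(p for p, s in zip(result.populations, signs) if s == "+")
    minus = tuple(p for p, s in zip(result.populations, signs) if s == "-")
    return DirectionCall(signs=signs, label="antiparallel", partition=(plus, minus),
                         populations=result.populations)


def analyze_windows(freqs: AlleleFrequencyTable, derived: list[str] | None = None,
                    snps_per_window: int = 200) -> list[EigenResult]:
    """Full per-window eigenanalysis; degenerate windows are logged and skipped."""
    results: list[EigenResult] = []
    n_degenerate = 0
    for window in build_windows(freqs, snps_per_window):
        try:
            results.append(eigen_decompose(normalize_rows(delta_matrix(freqs, window, derived))))
        except DegenerateWindowError as e:
            n_degenerate += 1
            logger.warning("skipping degenerate window: %s", e)
    if n_degenerate:
        logger.info("analyze_windows: skipped %d degenerate windows", n_degenerate)
    return results


def results_to_frame(results: list[EigenResult], eigenvector: int = 1) -> pd.DataFrame:
    """Tabulate per-window eigenvalues, loadings and direction labels."""
    rows = []
    for r in results:
        call = classify_direction(r, eigenvector)
        row = {"chrom": r.window.chrom, "start_bp": r.window.start_bp,
               "end_bp": r.window.end_bp, "n_snps": r.window.n_snps}
        for i, lam in enumerate(r.eigenvalues, 1):
            row[f"lambda{i}"] = lam
        for pop, v in zip(r.populations, r.loadings[:, eigenvector - 1]):
            row[f"loading_{pop}"] = v
        row["direction"] = call.label
        row["signs"] = "".join(call.signs)
        rows.append(row)
    return pd.DataFrame(rows)
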