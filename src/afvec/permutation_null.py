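"""Randomized null distribution for window eigenvalue statistics.

The null asks how much apparent co-direction of allele-frequency change
arises with the same genomic landscape and the same sampling design but no
real population structure in the changes: individuals are pooled across the
source and all derived populations, labels are reshuffled into groups of
the original sizes (the group that inherits the source label acts as the
pseudo-source), a window of ``n`` consecutive SNPs is drawn at a random
start position within a chromosome, and the full ΔAF → row-normalization →
eigendecomposition pipeline is recomputed. Repeating this many times gives
the null distribution of λ₁ (and of cumulative eigenvalue sums for higher
eigenvectors) against which observed windows are judged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eigen_windows import DegenerateWindowError, DeltaAFWindow, EigenResult, Window, \
    classify_direction, eigen_decompose, normalize_rows
from .genotype_io import MISSING, AlleleFrequencyTable, SampleRegistry, VariantTable, \
    compute_frequencies

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100  # attempts per permutation before giving up on degenerate data

__all__ = ["NullDistribution", "permute_once", "build_null", "empirical_pvalue", "call_outliers"]


@dataclass
class NullDistribution:
    """Permutation samples of eigenvalue statistics.

    ``eigenvalues`` has shape (n_perms, m), each row one permutation's
    descending spectrum. The test statistic for eigenvector k is λ₁ when
    k = 1 and the cumulative sum Σ_{i≤k} λᵢ otherwise.
    """

    eigenvalues: np.ndarray
    snps_per_window: int
    seed: int | None = None
    n_redraws: int = 0
    _sorted: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_perms(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def m(self) -> int:
        return self.eigenvalues.shape[1]

    def statistic_samples(self, eigenvector: int = 1) -> np.ndarray:
        """Sorted (ascending) null samples of the statistic for eigenvector k."""
        if not (1 <= eigenvector <= self.m):
            raise ValueError(f"eigenvector index must be in [1, {self.m}]")
        if eigenvector not in self._sorted:
            self._sorted[eigenvector] = np.sort(self.eigenvalues[:, :eigenvector].sum(axis=1))
        return self._sorted[eigenvector]

    def quantile(self, q: float, eigenvector: int = 1) -> float:
        return float(np.quantile(self.statistic_samples(eigenvector), q))

    def to_frame(self) -> pd.DataFrame:
        """Flat (eigenvector, sorted statistic samples) table for serialization."""
        rows = []
        for k in range(1, self.m + 1):
            for v in self.statistic_samples(k):
                rows.append({"eigenvector": k, "statistic": v})
        return pd.DataFrame(rows)


def _valid_starts(chrom: np.ndarray, snps_per_window: int) -> np.ndarray:
    """Start indices whose n-SNP window lies within a single chromosome."""
    starts: list[np.ndarray] = []
    offset = 0
    for c in pd.unique(chrom):
        n = int(np.sum(chrom == c))
        if n >= snps_per_window:
            starts.append(np.arange(offset, offset + n - snps_per_window + 1))
        offset += n
    if not starts:
        raise ValueError(f"no chromosome has >= {snps_per_window} SNPs")
    return np.concatenate(starts)


def _group_freqs(gw: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Polarized-allele frequency per site over one permuted sample group."""
    sub = gw[:, cols]
    called = 2 * (sub >= 0).sum(axis=1)
    if np.any(called == 0):
        return np.full(gw.shape[0], np.nan)
    return np.clip(sub, 0, None).sum(axis=1) / called


def permute_once(genotypes: np.ndarray, chrom: np.ndarray, registry: SampleRegistry,
                 snps_per_window: int, rng: np.random.Generator,
                 valid_starts: np.ndarray | None = None,
                 derived_only: bool = False) -> EigenResult:
    """One permutation: random window + shuffled individuals → eigenvalues.

    ``genotypes`` holds polarized-allele copy counts (rows = the retained,
    polarized sites of an :class:`AlleleFrequencyTable`; -1 = missing),
    columns ordered as ``registry.samples``. With ``derived_only`` the source
    individuals keep their label and only derived individuals are shuffled.

    Windows producing an all-zero ΔAF row (or an uncalled site in some
    pseudo-group) are redrawn, up to ``MAX_REDRAWS`` attempts.
    """
    if valid_starts is None:
        valid_starts = _valid_starts(chrom, snps_per_window)
    sizes = [registry.size(p) for p in registry.pop_labels]
    src_i = registry.pop_labels.index(registry.source)
    bounds = np.cumsum([0] + sizes)
    n_samples = bounds[-1]
    fixed = None
    if derived_only:
        fixed = np.arange(bounds[src_i], bounds[src_i + 1])

    for attempt in range(MAX_REDRAWS):
        start = int(valid_starts[rng.integers(len(valid_starts))])
        gw = genotypes[start:start + snps_per_window]
        if derived_only:
            movable = np.setdiff1d(np.arange(n_samples), fixed, assume_unique=True)
            shuffled = movable[rng.permutation(len(movable))]
            perm = np.empty(n_samples, dtype=np.intp)
            perm[fixed] = fixed
            perm[np.setdiff1d(np.arange(n_samples), fixed, assume_unique=True)] = shuffled
        else:
            perm = rng.permutation(n_samples)
        groups = [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        src = _group_freqs(gw, groups[src_i])
        if np.any(np.isnan(src)):
            continue
        rows = []
        ok = True
        for i, g in enumerate(groups):
            if i == src_i:
                continue
            f = _group_freqs(gw, g)
            if np.any(np.isnan(f)):
                ok = False
                break
            rows.append(f - src)
        if not ok:
            continue
        X = np.vstack(rows)
        window = Window(chrom=str(chrom[start]), start=start, stop=start + snps_per_window,
                        start_bp=0, end_bp=0)
        daf = DeltaAFWindow(window=window, X=X, populations=registry.derived)
        try:
            return eigen_decompose(normalize_rows(daf))
        except DegenerateWindowError:
            continue
    raise RuntimeError(f"permutation redraws exhausted after {MAX_REDRAWS} attempts "
                       "(data too degenerate to define change directions)")


def build_null(variants: VariantTable, registry: SampleRegistry,
               n_perms: int = 10_000, snps_per_window: int = 200,
               seed: int | None = None, min_called_fraction: float = 0.5,
               derived_only: bool = False,
               freqs: AlleleFrequencyTable | None = None) -> NullDistribution:
    """Run ``n_perms`` permutations and collect the eigenvalue samples.

    Permutations operate on genotypes (shuffling acts on individuals), using
    the same retained-site set and polarization as the observed analysis;
    pass the observed ``freqs`` to reuse its site filter, otherwise it is
    recomputed with ``min_called_fraction``.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    if freqs is None:
        freqs = compute_frequencies(variants, registry, min_called_fraction)
    # polarized copy counts: flip genotypes where the polarized allele is REF
    order = registry.column_indices(variants.samples)
    col_order = np.concatenate([order[p] for p in registry.pop_labels])
    g = variants.genotypes[freqs.site_index][:, col_order]
    flip = ~freqs.polarized_to_alt
    g = g.copy()
    g[flip] = np.where(g[flip] >= 0, 2 - g[flip], MISSING)
    valid_starts = _valid_starts(freqs.chrom, snps_per_window)
    rng = np.random.default_rng(seed)
    eigs = np.empty((n_perms, len(registry.derived)), dtype=np.float64)
    for i in range(n_perms):
        # columns of g follow registry.pop_labels blocks
        res = permute_once(g, freqs.chrom, registry, snps_per_window, rng,
                           valid_starts=valid_starts, derived_only=derived_only)
        eigs[i] = res.eigenvalues
    return NullDistribution(eigenvalues=eigs, snps_per_window=snps_per_window, seed=seed)


def empirical_pvalue(observed: EigenResult | float, null: NullDistribution,
                     eigenvector: int = 1,
                     snps_per_window: int | None = None) -> float:
    """Add-one empirical p-value: (1 + #{null ≥ obs}) / (1 + n_perms)."""
    if isinstance(observed, EigenResult):
        if observed.window.n_snps != null.snps_per_window:
            raise ValueError(
                f"window has {observed.window.n_snps} SNPs but null was built "
                f"with {null.snps_per_window}")
        stat = observed.statistic(eigenvector)
    else:
        stat = float(observed)
        if snps_per_window is not None and snps_per_window != null.snps_per_window:
            raise ValueError("window size mismatch between observed statistic and null")
    samples = null.statistic_samples(eigenvector)
    n_ge = len(samples) - np.searchsorted(samples, stat, side="left")
    return (1 + int(n_ge)) / (1 + null.n_perms)


def call_outliers(results: list[EigenResult], null: NullDistribution,
                  quantile: float = 0.999, eigenvector: int = 1) -> pd.DataFrame:
    """Windows whose statistic exceeds the null's empirical quantile.

    Returns one row per *outlier* window with its statistic, add-one p-value
    and parallel/antiparallel direction call.
    """
    if not (0.5 < quantile < 1):
        raise ValueError("quantile must be in (0.5, 1)")
    threshold = null.quantile(quantile, eigenvector)
    rows = []
    for r in results:
        stat = r.statistic(eigenvector)
        if stat > threshold:
            call = classify_direction(r, eigenvector)
            rows.append({
                "chrom": r.window.chrom, "start_bp": r.window.start_bp,
                "end_bp": r.window.end_bp, "statistic": stat,
                "pvalue": empirical_pvalue(r, null, eigenvector),
                "direction": call.label, "signs": "".join(call.signs),
            })
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "statistic",
                                       "pvalue", "direction", "signs"])
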