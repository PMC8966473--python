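"""Standardized selection coefficients from temporal allele-frequency change.

The per-SNP, per-population statistic is the additive selection coefficient
that would deterministically produce the observed change in log-odds of the
polarized (source-minor) allele over τ generations:

    s = (2/τ) · ln( p_τ q₀ / (p₀ q_τ) )

with p the polarized-allele frequency and q = 1 − p, at founding (0) and
sampling (τ). Under the diploid multiplicative model (genotype fitnesses
1 : e^{s/2} : e^{s}) the log-odds grow by exactly s/2 per generation, so
this inverts deterministic selection exactly and standardizes drift-driven
change for starting frequency. Because all populations share one
polarization, summing s within a SNP across populations is maximized by
large co-directional change; SNPs whose |summed s| exceed quantiles of the
census-conditioned neutral simulations are flagged in nested tiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .drift import SimulationBatch

__all__ = [
    "default_clamp",
    "standardized_s",
    "summed_s",
    "neutral_quantiles",
    "flag_outlier_snps",
    "selection_scan",
]

TIER_QUANTILES = (0.99, 0.999, 0.9999)


def default_clamp(n_chromosomes: int) -> float:
    """Frequency floor for fixed sites: 1/(2·n_chr + 1).

    An allele observed at frequency exactly 0 or 1 in a sample of n_chr
    chromosomes may simply sit below the detection limit; the clamp places
    it just beyond the resolvable range.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    return 1.0 / (2 * n_chromosomes + 1)


def standardized_s(p0, p_tau, tau: float, clamp: float):
    """s = (2/τ)·ln(p_τ(1−p₀)/(p₀(1−p_τ))), with fixed p_τ clamped.

    ``p_tau`` values of exactly 0 or 1 are replaced by ``clamp`` and
    ``1 − clamp``; founding frequencies of 0 or 1 are rejected (change from
    a fixed founder is undefined under this model). Scalar in → scalar out.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (0 < clamp < 0.5):
        raise ValueError("clamp must be in (0, 0.5)")
    scalar = np.isscalar(p0) and np.isscalar(p_tau)
    p0 = np.asarray(p0, dtype=np.float64)
    pt = np.asarray(p_tau, dtype=np.float64)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("founding frequency must lie strictly in (0, 1)")
    pt = np.where(pt == 0.0, clamp, pt)
    pt = np.where(pt == 1.0, 1.0 - clamp, pt)
    s = (2.0 / tau) * np.log(pt * (1.0 - p0) / (p0 * (1.0 - pt)))
    return float(s) if scalar else s


def summed_s(s_by_pop: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
    """Per-SNP arithmetic sum of signed s across populations.

    All populations must supply values for the same SNP set (and share the
    source-minor polarization, which is the caller's responsibility since
    raw arrays carry no allele labels).
    """
    if isinstance(s_by_pop, pd.DataFrame):
        arrays = [s_by_pop[c].to_numpy() for c in s_by_pop.columns]
    else:
        arrays = [np.asarray(v, dtype=np.float64) for v in s_by_pop.values()]
    if not arrays:
        raise ValueError("no populations supplied")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("SNP-set mismatch: populations differ in length")
    return np.sum(arrays, axis=0)


def neutral_quantiles(batches: dict[str, SimulationBatch], taus: dict[str, float],
                      clamp: float, quantiles=TIER_QUANTILES,
                      one_sided: bool = False) -> dict[float, float]:
    """Tail thresholds of |summed s| under the neutral drift simulations.

    Each population's batch is converted to per-replicate, per-SNP s against
    its own founding frequencies; replicate r of every population is paired
    (populations are founded independently, so any fixed pairing is
    exchangeable) and the signed s summed across populations. All summed
    values are pooled and the requested quantiles of |summed s| returned
    (of the signed sum when ``one_sided``).
    """
    pops = list(batches)
    if not pops:
        raise ValueError("no simulation batches supplied")
    r0 = batches[pops[0]].replicates
    n0 = batches[pops[0]].n_snps
    for p in pops:
        if batches[p].replicates != r0 or batches[p].n_snps != n0:
            raise ValueError(f"batch for {p!r} has mismatched replicate count or SNP count")
    total = np.zeros((r0, n0), dtype=np.float64)
    for p in pops:
        b = batches[p]
        total += standardized_s(b.founding[None, :], b.final, taus[p], clamp)
    pooled = total.ravel() if one_sided else np.abs(total.ravel())
    qs = sorted(quantiles)
    vals = np.quantile(pooled, qs)
    return {q: float(v) for q, v in zip(qs, vals)}


def flag_outlier_snps(observed: pd.DataFrame, thresholds: dict[float, float],
                      value_col: str = "summed_s") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign nested outlier tiers and per-chromosome observed/expected counts.

    ``observed`` needs columns ``chrom``, ``pos`` and ``value_col``. Each SNP
    gets the highest tier whose threshold its |summed s| exceeds (tiers are
    nested: a 0.9999 outlier is also a 0.999 and 0.99 outlier). The second
    frame reports, per chromosome and tier, the observed outlier count and
    the count expected from the tier's nominal tail fraction times the
    chromosome's SNP share.
    """
    out = observed.copy()
    absval = out[value_col].abs()
    qs = sorted(thresholds)
    tier = np.full(len(out), "none", dtype=object)
    for q in qs:  # ascending, so the highest exceeded tier wins
        tier[(absval > thresholds[q]).to_numpy()] = str(q)
    out["tier"] = tier
    rows = []
    for chrom, grp in out.groupby("chrom", sort=False):
        a = grp[value_col].abs()
        for q in qs:
            rows.append({
                "chrom": chrom, "quantile": q,
                "observed": int((a > thresholds[q]).sum()),
                "expected": (1.0 - q) * len(grp),
            })
    return out, pd.DataFrame(rows)


def selection_scan(freqs, taus: dict[str, float], clamp: float | None = None) -> pd.DataFrame:
    """Observed per-SNP s per derived population, plus the summed value.

    ``freqs`` is an :class:`~afvec.genotype_io.AlleleFrequencyTable`; the
    source sample frequency stands in for the founding frequency. Sites
    where the polarized allele is absent from the source sample cannot be
    scored and are dropped. Without an explicit ``clamp`` each population
    uses 1/(2·n_chr + 1) from its median called-chromosome count.
    """
    p0 = freqs.source_freq
    ok = (p0 > 0) & (p0 < 1)
    df = pd.DataFrame({"chrom": freqs.chrom[ok], "pos": freqs.pos[ok]})
    src_col = freqs.pops.index(freqs.source)
    cols = []
    for pop in freqs.derived:
        j = freqs.pops.index(pop)
        c = clamp if clamp is not None else default_clamp(
            int(np.median(freqs.called[:, j])))
        s = standardized_s(p0[ok], freqs.freqs[ok, j], taus[pop], c)
        df[f"s_{pop}"] = s
        cols.append(f"s_{pop}")
    df["summed_s"] = df[cols].sum(axis=1)
    df.attrs["clamp"] = clamp
    df.attrs["source_col"] = src_col
    return df
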