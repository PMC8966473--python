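"""Genotype input, polarized allele frequencies, and basic ΔAF summaries.

Reads multi-sample VCFs and sample→population maps, computes per-population
frequencies of the allele that is *minor in the source population* (the
polarization used throughout the package), and provides the simple
per-window mean |ΔAF| and fixed-difference summaries that precede the
multivariate analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1  # genotype sentinel: alternate-allele copies are 0/1/2, -1 = no call

__all__ = [
    "SampleRegistry",
    "VariantTable",
    "AlleleFrequencyTable",
    "read_popmap",
    "read_variants",
    "compute_frequencies",
    "count_fixed_source_minor",
    "windowed_delta_af",
]


# ---------------------------------------------------------------------------
# sample registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRegistry:
    """Sample→population assignment with one population flagged as the source.

    Parameters
    ----------
    populations
        Mapping population label → list of sample ids (insertion order is the
        canonical population order).
    source
        Label of the source (founder) population. The remaining populations
        are the "derived" (introduced) populations compared against it.
    """

    populations: dict[str, tuple[str, ...]]
    source: str

    def __post_init__(self) -> None:
        if self.source not in self.populations:
            raise ValueError(f"source population {self.source!r} not in popmap")
        seen: dict[str, str] = {}
        for pop, samples in self.populations.items():
            if len(samples) < 1:
                raise ValueError(f"population {pop!r} has no samples")
            for s in samples:
                if s in seen:
                    raise ValueError(f"sample {s!r} assigned to both {seen[s]!r} and {pop!r}")
                seen[s] = pop

    @property
    def pop_labels(self) -> list[str]:
        return list(self.populations)

    @property
    def derived(self) -> list[str]:
        return [p for p in self.populations if p != self.source]

    @property
    def sample_to_pop(self) -> dict[str, str]:
        return {s: p for p, ss in self.populations.items() for s in ss}

    @property
    def samples(self) -> list[str]:
        return [s for ss in self.populations.values() for s in ss]

    def size(self, pop: str) -> int:
        return len(self.populations[pop])

    def column_indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        """Column indices of each population within an ordered sample list."""
        pos = {s: i for i, s in enumerate(samples)}
        out = {}
        for pop, ss in self.populations.items():
            missing = [s for s in ss if s not in pos]
            if missing:
                raise KeyError(f"samples {missing} of population {pop!r} not present")
            out[pop] = np.array([pos[s] for s in ss], dtype=np.intp)
        return out


def read_popmap(path, source: str) -> SampleRegistry:
    """Read a two-column (sample, population) whitespace/tab-delimited table."""
    pops: dict[str, list[str]] = {}
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
            sample, pop = parts
            if sample in seen:
                raise ValueError(f"{path}:{ln}: duplicate sample {sample!r}")
            seen.add(sample)
            pops.setdefault(pop, []).append(sample)
    if source not in pops:
        raise ValueError(f"source population {source!r} not found in {path}")
    return SampleRegistry({p: tuple(s) for p, s in pops.items()}, source)


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Biallelic SNP genotypes as alternate-allele copy counts.

    ``genotypes`` is an int8 matrix of shape (n_sites, n_samples) holding
    0/1/2 alternate-allele copies, or -1 for missing calls. Positions are
    1-based and strictly increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.pos), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites × samples")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def subset(self, mask_or_index) -> "VariantTable":
        idx = np.asarray(mask_or_index)
        return VariantTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            samples=self.samples,
        )


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")
_SNP_ALLELES = frozenset("ACGT")


def read_variants(path, region: str | None = None,
                  registry: SampleRegistry | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF (plain or bgzipped).

    Multiallelic records and indels are skipped (counted and logged).
    ``region`` is ``"chrom"`` or ``"chrom:start-end"`` (1-based, inclusive)
    and is applied by streaming, so no index is required.

    Raises ``ValueError`` if the file's samples include one absent from a
    supplied registry.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if registry is not None:
        known = set(registry.sample_to_pop)
        for s in samples:
            if s not in known:
                raise ValueError(f"sample {s!r} in {path} is absent from the population map")

    want_chrom = want_lo = want_hi = None
    if region is not None:
        m = _REGION_RE.match(region)
        if not m:
            raise ValueError(f"malformed region {region!r}")
        want_chrom = m.group(1)
        if m.group(2):
            want_lo, want_hi = int(m.group(2)), int(m.group(3))

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        if want_chrom is not None:
            if v.CHROM != want_chrom:
                continue
            if want_lo is not None and not (want_lo <= v.POS <= want_hi):
                continue
        if (len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1
                or v.REF.upper() not in _SNP_ALLELES or v.ALT[0].upper() not in _SNP_ALLELES):
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt copies, 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(g)
    vcf.close()
    if n_skipped:
        logger.info("read_variants: skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    gt = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=gt,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# polarized allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-SNP, per-population frequency of the source-minor allele.

    ``freqs[i, j]`` is the frequency in population ``pops[j]`` of the allele
    that is minor in the source population at site ``i`` (ties at 0.5
    polarize to the alternate allele). ``called[i, j]`` is the number of
    non-missing chromosomes behind that estimate. ``polarized_to_alt[i]``
    records whether the reported allele is the VCF alternate allele.
    ``site_index`` maps rows back to the originating :class:`VariantTable`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    pops: list[str]
    source: str
    freqs: np.ndarray
    called: np.ndarray
    polarized_to_alt: np.ndarray
    site_index: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def derived(self) -> list[str]:
        return [p for p in self.pops if p != self.source]

    def _col(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in frequency table") from None

    def freq(self, pop: str) -> np.ndarray:
        return self.freqs[:, self._col(pop)]

    @property
    def source_freq(self) -> np.ndarray:
        return self.freq(self.source)

    @property
    def polarized_allele(self) -> np.ndarray:
        return np.where(self.polarized_to_alt, self.alt, self.ref)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                           "polarized_allele": self.polarized_allele})
        for j, p in enumerate(self.pops):
            df[f"freq_{p}"] = self.freqs[:, j]
        return df


def compute_frequencies(variants: VariantTable, registry: SampleRegistry,
                        min_called_fraction: float = 0.5) -> AlleleFrequencyTable:
    """Per-population allele frequencies, polarized to the source minor allele.

    Sites are dropped when any population has fewer than
    ``min_called_fraction`` of its chromosomes called, and when the same
    allele is fixed across *all* populations (such sites carry no change
    information and produce zero-length change vectors downstream).
    """
    if not (0 < min_called_fraction <= 1):
        raise ValueError("min_called_fraction must be in (0, 1]")
    cols = registry.column_indices(variants.samples)
    pops = registry.pop_labels
    n = variants.n_sites
    freqs = np.empty((n, len(pops)), dtype=np.float64)
    called = np.empty((n, len(pops)), dtype=np.int64)
    keep = np.ones(n, dtype=bool)
    for j, pop in enumerate(pops):
        sub = variants.genotypes[:, cols[pop]]
        ncalled = 2 * (sub >= 0).sum(axis=1)
        alt_copies = np.clip(sub, 0, None).sum(axis=1)
        called[:, j] = ncalled
        frac = ncalled / (2 * len(cols[pop]))
        keep &= frac >= min_called_fraction
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, j] = np.where(ncalled > 0, alt_copies / np.maximum(ncalled, 1), np.nan)
    if np.any(np.isnan(freqs[keep])):
        raise RuntimeError("population with zero called chromosomes at a retained site")
    # drop sites monomorphic for the same allele in every population
    mono = np.all(freqs == 0.0, axis=1) | np.all(freqs == 1.0, axis=1)
    n_mono = int((mono & keep).sum())
    keep &= ~mono
    n_dropped = n - int(keep.sum())
    if n_dropped:
        logger.info("compute_frequencies: dropped %d of %d sites (%d monomorphic)",
                    n_dropped, n, n_mono)
    idx = np.flatnonzero(keep)
    freqs = freqs[idx]
    called = called[idx]
    src = pops.index(registry.source)
    flip = freqs[:, src] > 0.5  # tie at 0.5 keeps the alternate allele
    freqs[flip] = 1.0 - freqs[flip]
    return AlleleFrequencyTable(
        chrom=variants.chrom[idx],
        pos=variants.pos[idx],
        ref=variants.ref[idx],
        alt=variants.alt[idx],
        pops=pops,
        source=registry.source,
        freqs=freqs,
        called=called,
        polarized_to_alt=~flip,
        site_index=idx,
    )


def count_fixed_source_minor(freqs: AlleleFrequencyTable, derived: str) -> int:
    """Number of sites where the source-minor allele is fixed in ``derived``."""
    return int(np.sum(freqs.freq(derived) == 1.0))


def windowed_delta_af(freqs: AlleleFrequencyTable, derived: str,
                      window_bp: int = 75_000) -> pd.DataFrame:
    """Mean |ΔAF| in non-overlapping windows of ``window_bp`` base pairs.

    Windows are half-open ``[start, start + window_bp)`` tiled from position
    1 on each chromosome; ΔAF is the derived-minus-source frequency of the
    polarized allele. Empty windows are reported with ``n_snps = 0`` and a
    missing statistic.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    dafs = np.abs(freqs.freq(derived) - freqs.source_freq)
    rows = []
    for chrom in pd.unique(freqs.chrom):
        m = freqs.chrom == chrom
        pos = freqs.pos[m]
        vals = dafs[m]
        widx = (pos - 1) // window_bp
        n_windows = int(widx.max()) + 1 if len(pos) else 0
        sums = np.bincount(widx, weights=vals, minlength=n_windows)
        counts = np.bincount(widx, minlength=n_windows)
        for w in range(n_windows):
            rows.append({
                "chrom": chrom,
                "start": 1 + w * window_bp,
                "end": 1 + (w + 1) * window_bp,
                "n_snps": int(counts[w]),
                "mean_abs_delta_af": sums[w] / counts[w] if counts[w] else np.nan,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_abs_delta_af"])
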