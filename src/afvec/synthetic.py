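"""Synthetic metapopulations with known truth for validating every analysis.

Emulates the study design the analyses assume: one large source population
and m derived populations founded from it, each evolving independently for
τ generations of binomial Wright-Fisher drift through a fluctuating census,
with ~20 diploid samples genotyped per population at unlinked biallelic
SNPs. Loci under parallel or antiparallel additive selection can be planted
with known per-population selection coefficients, and every dataset is
written alongside a truth table recording founder frequencies and the
planted effects.

Defaults mirror a riverine introduction experiment: four derived
populations, 20 samples each, seven generations, founding bottlenecks of
one-to-two hundred fish recovering into the high hundreds-to-thousands
with seasonal fluctuation (one population crashing after founding), and a
MAF-filtered SNP panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .drift import CensusTrajectory, sample_founder_frequencies, selection_update
from .genotype_io import MISSING, SampleRegistry, VariantTable

__all__ = ["SelectedLocus", "SyntheticDesign", "SyntheticDataset", "generate",
           "write_variants", "write_popmap", "write_census", "write_truth"]

# Census templates for the default four derived populations: founding
# bottleneck, growth to a peak within 2-3 generations, then seasonal
# fluctuation; the last one crashes after founding before recovering.
DEFAULT_CENSUS = {
    "D1": (200, 500, 1000, 1500, 1200, 800, 1100),
    "D2": (200, 600, 1200, 1800, 1500, 1000, 1300),
    "D3": (150, 400, 900, 1400, 600, 900, 1200),
    "D4": (100, 80, 300, 700, 500, 800, 1000),
}


@dataclass(frozen=True)
class SelectedLocus:
    """A planted selected SNP: global SNP index and per-population s.

    ``s`` is the selection coefficient on the founder-minor allele in each
    derived population (design order); equal signs plant parallel change,
    mixed signs antiparallel change.
    """

    snp_index: int
    s: tuple[float, ...]


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic metapopulation."""

    n_derived: int = 4
    samples_per_pop: int = 20
    n_chroms: int = 10
    snps_per_chrom: int = 1000
    chrom_length: int = 25_000_000
    ne: int = 1000                      # source Ne shaping the founder spectrum
    maf_min: float = 0.05               # emulates a MAF-filtered SNP panel
    census: dict[str, tuple[int, ...]] = field(default_factory=lambda: dict(DEFAULT_CENSUS))
    selected: list[SelectedLocus] = field(default_factory=list)
    missingness: float = 0.05
    source_label: str = "SRC"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_derived < 2:
            raise ValueError("need at least two derived populations")
        if len(self.census) != self.n_derived:
            # recycle templates for non-default population counts
            labels = [f"D{i + 1}" for i in range(self.n_derived)]
            tpl = list(self.census.values()) or list(DEFAULT_CENSUS.values())
            self.census = {lab: tpl[i % len(tpl)] for i, lab in enumerate(labels)}
        for loc in self.selected:
            if not (0 <= loc.snp_index < self.n_snps):
                raise ValueError(f"selected locus index {loc.snp_index} outside SNP panel")
            if len(loc.s) != self.n_derived:
                raise ValueError("selected locus needs one s per derived population")
            if any(abs(v) >= 2 for v in loc.s):
                raise ValueError("|s| must be < 2")

    @property
    def n_snps(self) -> int:
        return self.n_chroms * self.snps_per_chrom

    @property
    def derived_labels(self) -> list[str]:
        return list(self.census)


@dataclass
class SyntheticDataset:
    """Generated genotypes plus everything needed to check results."""

    variants: VariantTable
    registry: SampleRegistry
    census: dict[str, CensusTrajectory]
    truth: pd.DataFrame
    founder_minor_freq: np.ndarray      # founder frequency of the minor allele
    final_freqs: dict[str, np.ndarray]  # per-pop final alt-allele frequencies
    alt_is_minor: np.ndarray
    design: SyntheticDesign


def generate(design: SyntheticDesign, seed: int | None = None) -> SyntheticDataset:
    """Simulate genotypes for the source and all derived populations.

    Founder minor-allele frequencies come from the truncated neutral
    spectrum; each derived population's frequencies evolve through its
    census by binomial drift, with the deterministic selection update
    applied at planted loci before each binomial draw. Sampled genotypes
    are binomial(2, p) per individual, then thinned by uniform missingness.
    Fully deterministic under a fixed seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_snps
    f_minor = sample_founder_frequencies(n, ne=design.ne, rng=rng, maf_min=design.maf_min)
    for loc in design.selected:
        if f_minor[loc.snp_index] in (0.0, 1.0):
            raise ValueError(f"selected locus {loc.snp_index} fixed at founding")
    # which strand of the VCF is the minor allele, to exercise polarization
    alt_is_minor = rng.random(n) < 0.5
    p_alt0 = np.where(alt_is_minor, f_minor, 1.0 - f_minor)

    derived = design.derived_labels
    s_alt = {pop: np.zeros(n) for pop in derived}
    for loc in design.selected:
        for j, pop in enumerate(derived):
            # s is defined on the minor allele; flip where ALT is the major
            s_alt[pop][loc.snp_index] = loc.s[j] if alt_is_minor[loc.snp_index] else -loc.s[j]

    census = {pop: CensusTrajectory(pop, tuple(design.census[pop])) for pop in derived}
    final: dict[str, np.ndarray] = {}
    for pop in derived:
        p = p_alt0.copy()
        sel = s_alt[pop]
        has_sel = np.any(sel != 0)
        for n_t in census[pop].sizes:
            if has_sel:
                p = selection_update(p, sel)
            p = rng.binomial(2 * n_t, p) / (2.0 * n_t)
        final[pop] = p

    # genotype sampling: source drawn at founding frequencies, derived at final
    pops = [design.source_label] + derived
    freq_by_pop = {design.source_label: p_alt0, **final}
    k = design.samples_per_pop
    blocks = []
    samples: list[str] = []
    reg: dict[str, tuple[str, ...]] = {}
    for pop in pops:
        g = rng.binomial(2, freq_by_pop[pop][:, None], size=(n, k)).astype(np.int8)
        if design.missingness > 0:
            g[rng.random((n, k)) < design.missingness] = MISSING
        blocks.append(g)
        names = tuple(f"{pop}_{i + 1:03d}" for i in range(k))
        reg[pop] = names
        samples.extend(names)
    genotypes = np.hstack(blocks)

    # coordinates: sorted unique positions per chromosome
    chroms = np.repeat([f"chr{i + 1}" for i in range(design.n_chroms)], design.snps_per_chrom)
    pos = np.empty(n, dtype=np.int64)
    for i in range(design.n_chroms):
        lo, hi = i * design.snps_per_chrom, (i + 1) * design.snps_per_chrom
        p_ = rng.choice(np.arange(1, design.chrom_length, dtype=np.int64),
                        size=design.snps_per_chrom, replace=False)
        pos[lo:hi] = np.sort(p_)
    bases = np.array(list("ACGT"), dtype=object)
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4  # always differs from ref
    ref, alt = bases[ref_idx], bases[alt_idx]

    variants = VariantTable(chrom=np.asarray(chroms, dtype=object), pos=pos, ref=ref,
                            alt=alt, genotypes=genotypes, samples=samples)
    registry = SampleRegistry(reg, design.source_label)

    truth_rows = []
    for loc in design.selected:
        row = {"chrom": chroms[loc.snp_index], "pos": int(pos[loc.snp_index]),
               "snp_index": loc.snp_index,
               "founder_minor_freq": float(f_minor[loc.snp_index]),
               "pattern": "".join("+" if v > 0 else ("-" if v < 0 else "0") for v in loc.s)}
        for j, pop in enumerate(derived):
            row[f"s_{pop}"] = loc.s[j]
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    return SyntheticDataset(variants=variants, registry=registry, census=census,
                            truth=truth, founder_minor_freq=f_minor,
                            final_freqs=final, alt_is_minor=alt_is_minor, design=design)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_variants(table: VariantTable, path) -> None:
    """Write a VariantTable as a VCF v4.2 file with GT fields."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for chrom in pd.unique(table.chrom):
        length = int(table.pos[table.chrom == chrom].max()) + 1
        header.contigs.add(str(chrom), length=length)
    for s in table.samples:
        header.add_sample(s)
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(table.n_sites):
            rec = out.new_record(contig=str(table.chrom[i]), start=int(table.pos[i]) - 1,
                                 alleles=(str(table.ref[i]), str(table.alt[i])))
            for j, s in enumerate(table.samples):
                rec.samples[s]["GT"] = gt_codes[int(table.genotypes[i, j])]
            out.write(rec)


def write_popmap(registry: SampleRegistry, path) -> None:
    with open(path, "w") as fh:
        for pop, samples in registry.populations.items():
            for s in samples:
                fh.write(f"{s}\t{pop}\n")


def write_census(census: dict[str, CensusTrajectory], path) -> None:
    rows = [{"population": pop, "generation": g + 1, "N": n}
            for pop, traj in census.items() for g, n in enumerate(traj.sizes)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")
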