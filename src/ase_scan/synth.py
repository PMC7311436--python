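"""Synthetic-data generator: reference, SNP panel, phased genotypes, reads.

Emulates the study design behind chip-based allele-specific-expression
scans: a biallelic SNP panel with population allele frequencies, phased
diploid genotypes for a cohort drawn under Hardy-Weinberg equilibrium, and
RNA-seq-like reads over each heterozygous site with a planted allelic
ratio theta (theta = 0.5 balanced null, 0.5 < theta < 1 imbalanced,
theta = 1 monoallelic) plus uniform per-base sequencing error.

Every quantity is reproducible from ``SimulationConfig.seed``; independent
streams for reference, panel, truth and reads are spawned from a single
``numpy.random.SeedSequence`` so that stages can also be re-run alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import Panel

BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe a desk-scale cohort: 20 individuals genotyped at 200
    SNPs on two 50 kb autosomes, 100 bp single-end reads at a mean
    allele-informative coverage of 30x per heterozygous site, Illumina-like
    base error 1e-3.  ``theta_classes`` gives the mixture of planted
    allelic-ratio classes per site: 60% balanced (theta = 0.5), 25%
    imbalanced (theta = 0.8), 15% monoallelic (theta = 1.0).
    """

    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_sites: int = 200
    n_individuals: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    read_length: int = 100
    mean_coverage: float = 30.0
    base_error_rate: float = 0.001
    theta_classes: tuple[tuple[float, float], ...] = (
        (0.5, 0.60),
        (0.8, 0.25),
        (1.0, 0.15),
    )
    missing_rate: float = 0.0
    favored_allele: str = "hapA"  # hapA | ref | alt | major
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.n_sites, self.n_individuals) <= 0:
            raise ConfigurationError("all counts and lengths must be positive")
        if self.read_length <= 0 or self.read_length > self.chrom_length:
            raise ConfigurationError("read_length must be in [1, chrom_length]")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ConfigurationError("base_error_rate must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        props = [w for _, w in self.theta_classes]
        if abs(sum(props) - 1.0) > 1e-9 or any(w < 0 for w in props):
            raise ConfigurationError("theta class proportions must be >=0 and sum to 1")
        if any(not 0.5 <= t <= 1.0 for t, _ in self.theta_classes):
            raise ConfigurationError("theta must lie in [0.5, 1.0]")
        if self.favored_allele not in ("hapA", "ref", "alt", "major"):
            raise ConfigurationError("favored_allele must be hapA|ref|alt|major")

    def spawn_rngs(self, n: int = 4) -> list[np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(n)]


def _class_label(theta: float) -> str:
    if theta == 0.5:
        return "null"
    if theta == 1.0:
        return "monoallelic"
    return "imbalanced"


def generate_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random reference: one uniform A/C/G/T sequence per autosome.

    Chromosomes are named "1", "2", ... so the default autosome list of the
    genotype-QC stage retains them.
    """
    if rng is None:
        rng = config.spawn_rngs()[0]
    ref: dict[str, str] = {}
    for c in range(config.n_chromosomes):
        seq = BASES[rng.integers(0, 4, size=config.chrom_length)]
        ref[str(c + 1)] = seq.tobytes().decode("ascii")
    return ref


def _site_positions(config: SimulationConfig, chrom_len: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """0-based positions, pairwise spacing >= read_length and a read_length
    margin from both chromosome ends, so every full-length read covers at
    most one SNP and is never clipped."""
    margin = config.read_length
    slot = 2 * config.read_length
    first = margin
    last = chrom_len - margin - 1
    n_slots = max(0, (last - first) // slot + 1)
    if n > n_slots:
        raise ConfigurationError(
            f"cannot place {n} sites with spacing {config.read_length} on a "
            f"{chrom_len} bp chromosome"
        )
    chosen = np.sort(rng.choice(n_slots, size=n, replace=False))
    jitter = rng.integers(0, config.read_length, size=n)
    return first + chosen * slot + jitter


def generate_panel(
    reference: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Panel:
    """SNP panel + phased genotype matrix drawn under HWE.

    Per site: a minor-allele frequency uniform on ``maf_range``, the alt
    allele assigned to the minor or major side with equal probability, and
    each haplotype of each individual an independent Bernoulli(alt
    frequency) draw — i.e. HWE genotypes with uniformly random phase.
    Missing genotypes (both haplotypes) are injected at ``missing_rate``.
    """
    if rng is None:
        rng = config.spawn_rngs()[1]
    chroms = list(reference)
    # spread sites as evenly as possible across chromosomes
    per = np.full(len(chroms), config.n_sites // len(chroms))
    per[: config.n_sites % len(chroms)] += 1

    rows = []
    for chrom, n in zip(chroms, per):
        if n == 0:
            continue
        pos0 = _site_positions(config, len(reference[chrom]), int(n), rng)
        for p in pos0:
            ref_base = reference[chrom][p]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            rows.append((chrom, int(p) + 1, ref_base, alt))
    rows.sort(key=lambda r: (int(r[0]), r[1]))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    sites.insert(0, "site_id", [f"snp{i:05d}" for i in range(len(sites))])

    maf = rng.uniform(*config.maf_range, size=len(sites))
    alt_is_minor = rng.random(len(sites)) < 0.5
    sites["af_alt"] = np.where(alt_is_minor, maf, 1.0 - maf)

    shape = (config.n_individuals, len(sites))
    gt_a = (rng.random(shape) < sites["af_alt"].to_numpy()).astype(np.int8)
    gt_b = (rng.random(shape) < sites["af_alt"].to_numpy()).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(shape) < config.missing_rate
        gt_a[miss] = -1
        gt_b[miss] = -1

    individuals = [f"ind{i:03d}" for i in range(config.n_individuals)]
    return Panel(sites=sites, individuals=individuals, gt_a=gt_a, gt_b=gt_b)


def assign_truth(
    panel: Panel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Planted truth table: one row per heterozygous (individual, site).

    The allelic-ratio class is drawn once per site from ``theta_classes``;
    every heterozygous carrier of the site expresses that ratio.  The
    recorded ``theta`` is always the expected fraction of reads originating
    from haplotype A.  With the default ``favored_allele="hapA"`` the excess
    allele is hapA itself, so theta equals the class ratio; in
    "ref"/"alt"/"major" modes the class ratio is planted on the haplotype
    carrying that allele, and the recorded hapA fraction is flipped to
    1 - ratio for carriers phased the other way.
    """
    if rng is None:
        rng = config.spawn_rngs()[2]
    thetas = np.array([t for t, _ in config.theta_classes])
    props = np.array([w for _, w in config.theta_classes])
    site_theta = rng.choice(thetas, size=panel.n_sites, p=props / props.sum())

    major_is_alt = panel.sites["af_alt"].to_numpy() > 0.5
    het = panel.het_mask()
    rows = []
    for j in range(panel.n_sites):
        site_id = panel.sites.at[j, "site_id"]
        t = float(site_theta[j])
        for i in np.flatnonzero(het[:, j]):
            hap_a_allele = panel.gt_a[i, j]  # 0 ref / 1 alt
            if config.favored_allele == "hapA":
                theta_a = t
            elif config.favored_allele == "ref":
                theta_a = t if hap_a_allele == 0 else 1.0 - t
            elif config.favored_allele == "alt":
                theta_a = t if hap_a_allele == 1 else 1.0 - t
            else:  # major
                major_code = 1 if major_is_alt[j] else 0
                theta_a = t if hap_a_allele == major_code else 1.0 - t
            rows.append(
                (site_id, panel.individuals[i], theta_a, _class_label(t))
            )
    return pd.DataFrame(rows, columns=["site_id", "individual", "theta", "class_label"])


def generate_reads(
    reference: dict[str, str],
    panel: Panel,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Simulate reads per individual over their heterozygous sites.

    For each truth row: read count ~ Poisson(mean_coverage); each read's
    haplotype of origin ~ Bernoulli(theta) (theta = hapA fraction); the read
    sequence is copied from that haplotype at a uniform offset fully
    covering the site; substitution errors applied per base at
    ``base_error_rate``.  Returns ``{individual: [(name, sequence), ...]}``;
    names encode origin for debugging only and are never consumed
    downstream.
    """
    from .diploid import build_haplotypes

    if rng is None:
        rng = config.spawn_rngs()[3]
    L = config.read_length
    site_idx = {s: j for j, s in enumerate(panel.sites["site_id"])}
    reads: dict[str, list[tuple[str, str]]] = {ind: [] for ind in panel.individuals}

    for ind in panel.individuals:
        pair = build_haplotypes(reference, panel, ind)
        sub = truth[truth["individual"] == ind]
        for site_id, theta in zip(sub["site_id"], sub["theta"]):
            j = site_idx[site_id]
            chrom = panel.sites.at[j, "chrom"]
            pos0 = int(panel.sites.at[j, "pos"]) - 1
            if pos0 - L + 1 < 0 or pos0 + 1 > len(reference[chrom]) - L + 1:
                raise ConfigurationError("site too close to chromosome end for read_length")
            n = int(rng.poisson(config.mean_coverage))
            if n == 0:
                continue
            from_a = rng.random(n) < theta
            starts = rng.integers(pos0 - L + 1, pos0 + 1, size=n)
            for r in range(n):
                hap_seq = pair.seq_a[chrom] if from_a[r] else pair.seq_b[chrom]
                s = int(starts[r])
                seq = hap_seq[s : s + L]
                if config.base_error_rate > 0:
                    err = rng.random(L) < config.base_error_rate
                    if err.any():
                        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                        for k in np.flatnonzero(err):
                            choices = [b for b in b"ACGT" if bytes([b]) != arr[k]]
                            arr[k] = bytes([rng.choice(choices)])
                        seq = arr.tobytes().decode("ascii")
                name = f"{ind}|{site_id}|{'A' if from_a[r] else 'B'}|{r}"
                reads[ind].append((name, seq))
    return reads


def simulate_counts(
    panel: Panel,
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    fixed_coverage: int | None = None,
) -> pd.DataFrame:
    """Counts-level shortcut: draw allele counts directly from truth theta.

    Per truth row, total reads n ~ Poisson(mean_coverage) (or exactly
    ``fixed_coverage``), hapA reads ~ Binomial(n, theta), mapped onto
    ref/alt by the carrier's phase.  Statistically equivalent to error-free
    read simulation followed by perfect-match counting; used for
    calibration studies where per-base realism is irrelevant.
    """
    if rng is None:
        rng = config.spawn_rngs()[3]
    site_idx = {s: j for j, s in enumerate(panel.sites["site_id"])}
    ind_idx = {s: i for i, s in enumerate(panel.individuals)}
    rows = []
    for site_id, ind, theta in zip(truth["site_id"], truth["individual"], truth["theta"]):
        j, i = site_idx[site_id], ind_idx[ind]
        n = fixed_coverage if fixed_coverage is not None else int(rng.poisson(config.mean_coverage))
        if n == 0:
            continue
        k_a = int(rng.binomial(n, theta))
        ref_count = k_a if panel.gt_a[i, j] == 0 else n - k_a
        rows.append(
            (
                ind,
                site_id,
                panel.sites.at[j, "chrom"],
                int(panel.sites.at[j, "pos"]),
                ref_count,
                n - ref_count,
            )
        )
    return pd.DataFrame(
        rows, columns=["individual", "site_id", "chrom", "pos", "ref_count", "alt_count"]
    )


def generate_gene_models(reference: dict[str, str], config: SimulationConfig):
    """Synthetic gene models tiling the reference for annotation runs.

    Alternating-strand two-exon genes with 5'UTR / CDS / 3'UTR structure
    are placed end to end along each chromosome, leaving intergenic gaps,
    so planted SNPs fall into every consequence class.  Purely synthetic
    stand-ins for a real transcript database.
    """
    from .annotate import GeneModel, Transcript

    models = []
    g = 0
    # genomic layout (0-based half-open, strand-independent):
    # exon1 = left UTR (150) + CDS chunk (300); intron (600);
    # exon2 = CDS chunk (300) + right UTR (450); CDS total 600 (div. by 3)
    lutr, cds1, intron, cds2, rutr = 150, 300, 600, 300, 450
    for chrom, seq in reference.items():
        pos = 200
        while pos + (lutr + cds1 + intron + cds2 + rutr) < len(seq) - 200:
            strand = "+" if g % 2 == 0 else "-"
            e1 = (pos, pos + lutr + cds1)
            e2 = (e1[1] + intron, e1[1] + intron + cds2 + rutr)
            left_utr = [(pos, pos + lutr)]
            right_utr = [(e2[0] + cds2, e2[1])]
            cds = [(pos + lutr, e1[1]), (e2[0], e2[0] + cds2)]
            gene_id = f"gene{g:04d}"
            tx = Transcript(
                transcript_id=f"{gene_id}.t1",
                exons=[e1, e2],
                cds=cds,
                utr5=left_utr if strand == "+" else right_utr,
                utr3=right_utr if strand == "+" else left_utr,
            )
            models.append(
                GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=[tx])
            )
            g += 1
            pos = e2[1] + 800  # intergenic gap
    return models
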