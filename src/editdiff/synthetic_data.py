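"""Self-contained synthetic RNA-editing cohorts with planted truth.

The generator emulates the structure of a two-cohort brain RNA-Seq study:
a small genome of single-exon protein-coding genes on alternating strands,
A-to-I editing sites planted inside coding regions with per-group
"sample is edited" prevalences and a per-read editing rate, heterozygous
and homozygous SNV positions that masquerade as editing until the SNV
filter removes them, uniform sequencing error, and per-sample library
sizes that vary around a mean coverage.  Reads are emitted as aligned,
coordinate-sorted proper pairs (alignment itself is upstream of this
pipeline), so every downstream module is exercisable without any external
data.
"""

from __future__ import annotations

import dataclasses
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from . import formats_io
from .diff_stats import (
    CASE,
    CONTROL,
    BurdenResult,
    ContingencyRecord,
    SampleProfile,
    burden_per_sample,
    differential_table,
)
from .filter_cascade import apply_filter_cascade
from .formats_io import (
    CodingAnnotation,
    KnownEditingCatalog,
    SnvCatalog,
    complement_base,
)
from .site_caller import FilterConfig, call_sample

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class EditingSiteSpec:
    """One planted editing site: per-group Bernoulli prevalences of a
    sample being edited, and the per-read editing rate within an edited
    sample."""

    prevalence_control: float
    prevalence_case: float
    editing_rate: float = 0.8
    position: Optional[int] = None  # 1-based; auto-placed inside a CDS if None

    def __post_init__(self):
        for name in ("prevalence_control", "prevalence_case"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.editing_rate <= 1.0:
            raise ValueError("editing_rate must be in (0, 1]")

    @property
    def is_differential(self) -> bool:
        return self.prevalence_control != self.prevalence_case


@dataclass(frozen=True)
class SnvSpec:
    """A genomic SNV position with population genotype frequencies."""

    het_fraction: float = 0.5
    hom_alt_fraction: float = 0.25
    position: Optional[int] = None

    def __post_init__(self):
        if self.het_fraction + self.hom_alt_fraction > 1.0:
            raise ValueError("genotype fractions exceed 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Truth parameters of a synthetic cohort.

    Defaults mirror the emulated study: 44 control vs 29 case samples,
    100 nt paired-end reads, MAPQ 60 alignments, ~0.1% uniform sequencing
    error.  Tests and desk-scale runs use smaller cohorts via the factory
    helpers below.
    """

    editing_sites: Tuple[EditingSiteSpec, ...]
    snvs: Tuple[SnvSpec, ...] = ()
    seed: int = 0
    n_control: int = 44
    n_case: int = 29
    n_genes: int = 6
    gene_length: int = 600
    intergenic: int = 200
    read_length: int = 100
    fragment_length: int = 250
    mean_coverage: float = 50.0
    library_size_range: Tuple[float, float] = (0.7, 1.3)
    sequencing_error_rate: float = 0.001
    base_quality: int = 40
    known_fraction: float = 1.0
    chrom: str = "chrS"

    def __post_init__(self):
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("need at least one sample per group")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        if self.fragment_length < 2 * self.read_length - self.read_length:
            raise ValueError("fragment shorter than a read")
        if self.gene_length < self.fragment_length:
            raise ValueError("gene_length must accommodate one fragment")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise ValueError("known_fraction must be in [0, 1]")

    @property
    def genome_length(self) -> int:
        return self.n_genes * (self.gene_length + self.intergenic) + self.intergenic


@dataclass(frozen=True)
class PlacedSite:
    position: int  # 1-based
    gene: str
    strand: str
    spec: EditingSiteSpec
    known: bool
    forward_ref: str  # 'A' on + genes, 'T' on - genes
    forward_alt: str  # 'G' / 'C'


@dataclass(frozen=True)
class PlacedSnv:
    position: int
    gene: str
    strand: str
    spec: SnvSpec
    forward_ref: str
    forward_alt: str


@dataclass
class ReferenceBundle:
    """Reference genome plus the catalogs the pipeline consumes, with the
    planted-site layout."""

    config: SimulationConfig
    sequence: str
    annotation: CodingAnnotation
    known: KnownEditingCatalog
    snv_catalog: SnvCatalog
    sites: List[PlacedSite]
    snvs: List[PlacedSnv]
    paths: Dict[str, Path] = field(default_factory=dict)

    @property
    def sequences(self) -> Dict[str, str]:
        return {self.config.chrom: self.sequence}

    def site_genes(self) -> Dict[Tuple[str, int], str]:
        return {(self.config.chrom, s.position): s.gene for s in self.sites}


@dataclass
class TruthTable:
    """Planted truth: per-sample edited indicators, per-site prevalences
    and the expected differential flag."""

    edited: Dict[Tuple[str, int], bool]  # (sample_id, position) -> edited
    sites: List[PlacedSite]
    snv_positions: List[int]

    def differential_positions(self) -> List[int]:
        return [s.position for s in self.sites if s.spec.is_differential]

    def null_positions(self) -> List[int]:
        return [s.position for s in self.sites if not s.spec.is_differential]


def _gene_bounds(config: SimulationConfig, i: int) -> Tuple[int, int]:
    start0 = config.intergenic + i * (config.gene_length + config.intergenic)
    return start0, start0 + config.gene_length


def simulate_reference(config: SimulationConfig, outdir=None) -> ReferenceBundle:
    """Build the genome, annotation and catalogs; deterministic given the seed.

    Genes alternate strands; editing sites get reference base A on +
    genes and T on − genes (so − sites appear as T→C on the forward
    reference and exercise the strand-complement rule).  The first
    ``known_fraction`` of the editing sites go into the known-site
    catalog.  If ``outdir`` is given, FASTA/GTF/TSV/VCF files are written
    there.
    """
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.genome_length)

    ann = CodingAnnotation()
    strands = []
    for i in range(config.n_genes):
        s0, e0 = _gene_bounds(config, i)
        strand = "+" if i % 2 == 0 else "-"
        strands.append(strand)
        ann.add(config.chrom, s0, e0, f"GENE{i + 1}", strand)

    # deterministic collision-free placement inside coding regions
    margin = 5
    taken = set()

    def place(gene_idx: int) -> int:
        s0, e0 = _gene_bounds(config, gene_idx)
        while True:
            pos1 = int(rng.integers(s0 + margin, e0 - margin)) + 1
            if pos1 not in taken:
                taken.add(pos1)
                return pos1

    def locate(pos1: int) -> Tuple[int, str]:
        for i in range(config.n_genes):
            s0, e0 = _gene_bounds(config, i)
            if s0 < pos1 <= e0:
                return i, strands[i]
        raise ValueError(f"configured site at {pos1} lies outside every coding exon")

    n_known = int(round(len(config.editing_sites) * config.known_fraction))
    sites: List[PlacedSite] = []
    for j, spec in enumerate(config.editing_sites):
        if spec.position is None:
            gi = j % config.n_genes
            pos1 = place(gi)
        else:
            pos1 = spec.position
            gi, _ = locate(pos1)
            if pos1 in taken:
                raise ValueError(f"duplicate configured position {pos1}")
            taken.add(pos1)
        strand = strands[gi]
        fwd_ref = "A" if strand == "+" else "T"
        fwd_alt = "G" if strand == "+" else "C"
        seq[pos1 - 1] = fwd_ref
        sites.append(
            PlacedSite(
                position=pos1, gene=f"GENE{gi + 1}", strand=strand, spec=spec,
                known=j < n_known, forward_ref=fwd_ref, forward_alt=fwd_alt,
            )
        )

    snvs: List[PlacedSnv] = []
    for j, spec in enumerate(config.snvs):
        if spec.position is None:
            gi = j % config.n_genes
            pos1 = place(gi)
        else:
            pos1 = spec.position
            gi, _ = locate(pos1)
            taken.add(pos1)
        strand = strands[gi]
        fwd_ref = "A" if strand == "+" else "T"
        fwd_alt = "G" if strand == "+" else "C"
        seq[pos1 - 1] = fwd_ref
        snvs.append(
            PlacedSnv(
                position=pos1, gene=f"GENE{gi + 1}", strand=strand, spec=spec,
                forward_ref=fwd_ref, forward_alt=fwd_alt,
            )
        )

    known = KnownEditingCatalog()
    for s in sites:
        if s.known:
            # catalogs list A-to-I events as AG on the gene strand
            known.add(config.chrom, s.position, s.strand, "AG")

    snv_catalog = SnvCatalog()
    for v in snvs:
        snv_catalog.add(config.chrom, v.position, v.forward_ref, v.forward_alt)

    bundle = ReferenceBundle(
        config=config, sequence="".join(seq), annotation=ann, known=known,
        snv_catalog=snv_catalog, sites=sites, snvs=snvs,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        with open(fasta, "wt") as fh:
            fh.write(f">{config.chrom}\n")
            for i in range(0, len(bundle.sequence), 80):
                fh.write(bundle.sequence[i : i + 80] + "\n")
        pysam.faidx(str(fasta))
        gtf = outdir / "genes.gtf"
        formats_io.write_gtf(ann, gtf)
        known_tsv = outdir / "known_sites.tsv"
        formats_io.write_known_sites(known, known_tsv)
        vcf = outdir / "snvs.vcf"
        formats_io.write_snv_vcf(snv_catalog, vcf)
        bundle.paths = {"fasta": fasta, "gtf": gtf, "known": known_tsv, "vcf": vcf}
    return bundle


@dataclass
class SampleSim:
    sample_id: str
    group: str
    bam_path: Path
    library_size: int
    edited: Dict[int, bool]  # position -> sample edited
    genotypes: Dict[int, int]  # position -> alt-allele dose (0/1/2)


def _sample_rng(config: SimulationConfig, sample_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 7919, sample_index])


def simulate_sample(
    config: SimulationConfig,
    reference: ReferenceBundle,
    sample_index: int,
    group: str,
    outdir,
) -> SampleSim:
    """Emit one sample's coordinate-sorted, indexed BAM plus its truth rows.

    Editing and heterozygous-SNV alleles are drawn per cDNA fragment (both
    mates of a pair report the same molecule); sequencing errors are drawn
    per read base, flipping to a uniform wrong base.
    """
    if group not in (CONTROL, CASE):
        raise ValueError(f"unknown group {group!r}")
    rng = _sample_rng(config, sample_index)
    chrom = config.chrom
    rl, fl = config.read_length, config.fragment_length
    seq = np.frombuffer(reference.sequence.encode(), dtype="S1")

    edited = {
        s.position: bool(
            rng.random()
            < (s.spec.prevalence_control if group == CONTROL else s.spec.prevalence_case)
        )
        for s in reference.sites
    }
    genotypes = {}
    for v in reference.snvs:
        u = rng.random()
        if u < v.spec.hom_alt_fraction:
            genotypes[v.position] = 2
        elif u < v.spec.hom_alt_fraction + v.spec.het_fraction:
            genotypes[v.position] = 1
        else:
            genotypes[v.position] = 0

    factor = rng.uniform(*config.library_size_range)
    coding_len = config.n_genes * config.gene_length
    n_fragments = max(1, int(round(config.mean_coverage * coding_len / (2 * rl) * factor)))

    site_by_pos = {s.position: s for s in reference.sites}
    snv_by_pos = {v.position: v for v in reference.snvs}
    special_positions = sorted(site_by_pos.keys() | snv_by_pos.keys())
    eps = config.sequencing_error_rate

    gene_idx = rng.integers(0, config.n_genes, size=n_fragments)
    offsets = rng.integers(0, config.gene_length - fl + 1, size=n_fragments)

    from bisect import bisect_left, bisect_right

    reads = []  # (pos0, qname, flag, seq, mate_pos0)
    for i in range(n_fragments):
        g = int(gene_idx[i])
        s0, _ = _gene_bounds(config, g)
        start0 = s0 + int(offsets[i])
        frag = seq[start0 : start0 + fl].astype("U1").copy()
        lo1, hi1 = start0 + 1, start0 + fl  # 1-based inclusive span
        lo_i = bisect_left(special_positions, lo1)
        hi_i = bisect_right(special_positions, hi1)
        for pos1 in special_positions[lo_i:hi_i]:
            site = site_by_pos.get(pos1)
            if site is not None:
                if edited[pos1] and rng.random() < site.spec.editing_rate:
                    frag[pos1 - 1 - start0] = site.forward_alt
                continue
            snv = snv_by_pos[pos1]
            dose = genotypes[pos1]
            if dose == 2 or (dose == 1 and rng.random() < 0.5):
                frag[pos1 - 1 - start0] = snv.forward_alt
        mate1 = frag[:rl].copy()
        mate2 = frag[fl - rl :].copy()
        for mate in (mate1, mate2):
            n_err = rng.binomial(rl, eps)
            if n_err:
                idx = rng.choice(rl, size=n_err, replace=False)
                for q in idx:
                    others = [b for b in "ACGT" if b != mate[q]]
                    mate[q] = others[int(rng.integers(3))]
        qname = f"frag{i}"
        reads.append((start0, qname, 99, "".join(mate1), start0 + fl - rl))
        reads.append((start0 + fl - rl, qname, 147, "".join(mate2), start0))

    reads.sort(key=lambda r: (r[0], r[1], r[2]))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_id = f"{group}_{sample_index:03d}"
    bam_path = outdir / f"{sample_id}.bam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": config.genome_length}],
    }
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for pos0, qname, flag, bases, mate_pos0 in reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = f"{rl}M"
            a.query_sequence = bases
            a.query_qualities = pysam.qualitystring_to_array(
                chr(config.base_quality + 33) * rl
            )
            a.next_reference_id = 0
            a.next_reference_start = mate_pos0
            a.template_length = fl if flag == 99 else -fl
            a.set_tag("NH", 1)
            bam.write(a)
    pysam.index(str(bam_path))

    return SampleSim(
        sample_id=sample_id, group=group, bam_path=bam_path,
        library_size=len(reads), edited=edited, genotypes=genotypes,
    )


@dataclass
class EndToEndResult:
    differential: List[ContingencyRecord]
    burden: BurdenResult
    profiles_matched: List[SampleProfile]
    profiles_all: List[SampleProfile]
    truth: TruthTable
    reference: ReferenceBundle
    recovery: Dict[str, object]


def run_end_to_end(
    config: SimulationConfig,
    workdir=None,
    alpha: float = 0.05,
    filter_config: Optional[FilterConfig] = None,
) -> EndToEndResult:
    """Simulate a cohort and run call → filter → differential/burden on it.

    The recovery report compares BH-significant sites (``alpha``) with the
    planted differential flags.
    """
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="editdiff_sim_")
        workdir = tmp.name
    try:
        workdir = Path(workdir)
        ref = simulate_reference(config, outdir=None)
        fc = filter_config or FilterConfig()

        groups = [CONTROL] * config.n_control + [CASE] * config.n_case
        profiles_matched, profiles_all = [], []
        truth_edited = {}
        for idx, group in enumerate(groups):
            sim = simulate_sample(config, ref, idx, group, workdir / "bam")
            calls = call_sample(sim.bam_path, ref.sequences, ref.annotation, fc)
            sets = apply_filter_cascade(calls, ref.annotation, ref.snv_catalog, ref.known)
            matched_sites = {c.site for c in sets.known_matched}
            all_sites = {c.site for c in sets.coding_a_to_i}
            profiles_matched.append(
                SampleProfile(sim.sample_id, group, matched_sites, sim.library_size)
            )
            profiles_all.append(
                SampleProfile(sim.sample_id, group, all_sites, sim.library_size)
            )
            for pos, flag in sim.edited.items():
                truth_edited[(sim.sample_id, pos)] = flag
            sim.bam_path.unlink(missing_ok=True)
            Path(str(sim.bam_path) + ".bai").unlink(missing_ok=True)

        tested = sorted(set().union(*(p.edited_sites for p in profiles_matched)))
        records = differential_table(
            profiles_matched, tested, m_total=len(tested), genes=ref.site_genes()
        )
        burden = burden_per_sample(profiles_all)
        truth = TruthTable(
            edited=truth_edited, sites=ref.sites,
            snv_positions=[v.position for v in ref.snvs],
        )

        significant = {
            (r.chrom, r.position) for r in records if r.p_adjusted <= alpha
        }
        true_diff = {(config.chrom, p) for p in truth.differential_positions()}
        null_sites = {(config.chrom, p) for p in truth.null_positions()}
        recovery = {
            "n_tested": len(records),
            "n_significant": len(significant),
            "n_true_differential": len(true_diff),
            "n_true_detected": len(significant & true_diff),
            "n_false_positive": len(significant & null_sites),
            "significant_null_fraction": (
                len(significant & null_sites) / len(null_sites) if null_sites else 0.0
            ),
        }
        return EndToEndResult(
            differential=records, burden=burden,
            profiles_matched=profiles_matched, profiles_all=profiles_all,
            truth=truth, reference=ref, recovery=recovery,
        )
    finally:
        if tmp is not None:
            tmp.cleanup()


def null_fdr_fractions(
    config: SimulationConfig, n_replicates: int, alpha: float = 0.05
) -> List[float]:
    """Fraction of tested sites called significant in each of
    ``n_replicates`` independent end-to-end runs of an all-null cohort.

    Replicate r runs with seed ``config.seed + r``; under the null every
    fraction estimates the per-site false-positive rate after BH.
    """
    for s in config.editing_sites:
        if s.is_differential:
            raise ValueError("null_fdr_fractions requires an all-null configuration")
    fractions = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        res = run_end_to_end(cfg, alpha=alpha)
        n = res.recovery["n_tested"]
        fractions.append(res.recovery["n_significant"] / n if n else 0.0)
    return fractions


# ---------------------------------------------------------------------------
# Study-condition factories (desk scale)
# ---------------------------------------------------------------------------


def recovery_config(seed: int = 1) -> SimulationConfig:
    """20+20 cohort, coverage 50: 5 differential sites (prevalence 0.9 vs
    0.2, per-read rate 0.8) among 40 null sites (prevalence 0.3)."""
    sites = tuple(
        EditingSiteSpec(0.9, 0.2, 0.8) for _ in range(5)
    ) + tuple(EditingSiteSpec(0.3, 0.3, 0.8) for _ in range(40))
    return SimulationConfig(
        editing_sites=sites, seed=seed, n_control=20, n_case=20,
        n_genes=6, gene_length=600, mean_coverage=50.0, known_fraction=1.0,
    )


def null_config(seed: int = 1) -> SimulationConfig:
    """All-null desk-scale cohort for false-discovery calibration:
    10+10 samples, 12 null sites at prevalence 0.3, coverage 25."""
    sites = tuple(EditingSiteSpec(0.3, 0.3, 0.8) for _ in range(12))
    return SimulationConfig(
        editing_sites=sites, seed=seed, n_control=10, n_case=10,
        n_genes=3, gene_length=500, mean_coverage=25.0, known_fraction=1.0,
    )


def burden_config(seed: int = 1) -> SimulationConfig:
    """Cohort with globally lower case prevalence (0.7 vs 0.35 at every
    site) for the editing-burden directionality check."""
    sites = tuple(EditingSiteSpec(0.7, 0.35, 0.8) for _ in range(30))
    return SimulationConfig(
        editing_sites=sites, seed=seed, n_control=15, n_case=15,
        n_genes=6, gene_length=600, mean_coverage=30.0, known_fraction=0.5,
    )
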