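"""Readers and writers for the standard formats the pipeline touches.

All user-facing coordinates are 1-based (the convention of VCF, GTF and the
result tables); intervals are stored half-open 0-based internally, and the
readers/writers are the only place the conversion happens.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: the 12 possible single-base substitutions, two-letter ref→alt codes
SUBSTITUTION_CODES = frozenset(
    a + b for a in "ACGT" for b in "ACGT" if a != b
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement_substitution(code: str) -> str:
    """Complement a two-letter substitution code, e.g. ``TC`` → ``AG``."""
    return _COMPLEMENT[code[0]] + _COMPLEMENT[code[1]]


def complement_base(base: str) -> str:
    return _COMPLEMENT[base]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


def _open_text(path) -> Iterator[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# SNV catalog (gnomAD-like VCF)
# ---------------------------------------------------------------------------


@dataclass
class SnvCatalog:
    """Positions catalogued as genomic single-nucleotide variants.

    Candidate editing sites falling on these positions are treated as
    genetic variation rather than editing and excluded.  Membership is
    positional by default; ref/alt alleles are retained for the optional
    allele-aware mode.
    """

    positions: set = field(default_factory=set)
    alleles: dict = field(default_factory=dict)  # (chrom, pos) -> set of (ref, alt)

    def add(self, chrom: str, pos: int, ref: Optional[str] = None, alt: Optional[str] = None):
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        key = (chrom, int(pos))
        self.positions.add(key)
        if ref is not None and alt is not None:
            self.alleles.setdefault(key, set()).add((ref, alt))

    def __contains__(self, key) -> bool:
        return tuple(key) in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, chrom: str, pos: int, ref: Optional[str] = None,
                alt: Optional[str] = None, allele_aware: bool = False) -> bool:
        """True if the site is catalogued; with ``allele_aware`` the ref/alt
        pair must also match one of the catalogued allele pairs."""
        key = (chrom, int(pos))
        if key not in self.positions:
            return False
        if not allele_aware:
            return True
        known = self.alleles.get(key)
        if not known:  # positional-only record: fall back to positional match
            return True
        return (ref, alt) in known


def read_snv_catalog(path) -> SnvCatalog:
    """Load SNV positions from a VCF (plain or bgzipped).

    Multi-allelic records collapse to one positional entry; every ALT
    allele is retained for the allele-aware mode.
    """
    from cyvcf2 import VCF

    catalog = SnvCatalog()
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports errors without line numbers
        raise FormatError(f"{path}: malformed VCF header ({exc})") from None
    try:
        for n, rec in enumerate(vcf, start=1):
            for alt in rec.ALT or [None]:
                catalog.add(rec.CHROM, rec.POS, rec.REF, alt)
    except Exception as exc:
        raise FormatError(f"{path}: malformed VCF record near record {n} ({exc})") from None
    finally:
        vcf.close()
    return catalog


def write_snv_vcf(catalog: SnvCatalog, path) -> None:
    """Write a minimal VCF 4.2 with one row per catalogued allele."""
    rows = []
    for chrom, pos in sorted(catalog.positions):
        pairs = sorted(catalog.alleles.get((chrom, pos), {("N", "N")}))
        for ref, alt in pairs:
            rows.append(f"{chrom}\t{pos}\t.\t{ref or 'N'}\t{alt or 'N'}\t.\tPASS\t.")
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in rows:
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Known editing sites (REDIportal-like TSV)
# ---------------------------------------------------------------------------


@dataclass
class KnownEditingCatalog:
    """Catalog of known editing positions: (chrom, pos) → (strand, substitution)."""

    entries: dict = field(default_factory=dict)

    def add(self, chrom: str, pos: int, strand: str, substitution: str):
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {strand!r}")
        if substitution not in SUBSTITUTION_CODES:
            raise ValueError(f"invalid substitution code {substitution!r}")
        key = (chrom, int(pos))
        if key in self.entries and self.entries[key] != (strand, substitution):
            logger.warning("duplicate known-site entry at %s:%d, keeping the later one", chrom, pos)
        self.entries[key] = (strand, substitution)

    def __contains__(self, key) -> bool:
        return tuple(key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, chrom: str, pos: int):
        return self.entries.get((chrom, int(pos)))


def read_known_sites(path) -> KnownEditingCatalog:
    """Read a known-editing-site TSV with columns chrom, position, strand,
    substitution.  A header line is permitted (detected by a non-numeric
    position field).  Later duplicate rows overwrite earlier ones."""
    catalog = KnownEditingCatalog()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"\t|\s+", line.strip())
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, strand, subst = fields[:4]
            if lineno == 1 and not pos_s.isdigit():
                continue  # header
            if not pos_s.isdigit():
                raise FormatError(f"{path}:{lineno}: non-numeric position {pos_s!r}")
            # normalize unicode minus from copy-pasted tables
            strand = strand.replace("−", "-")
            try:
                catalog.add(chrom, int(pos_s), strand, subst.upper())
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return catalog


def write_known_sites(catalog: KnownEditingCatalog, path) -> None:
    with open(path, "wt") as fh:
        fh.write("chrom\tposition\tstrand\tsubstitution\n")
        for (chrom, pos), (strand, subst) in sorted(catalog.entries.items()):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{subst}\n")


# ---------------------------------------------------------------------------
# Coding annotation (GTF / BED6)
# ---------------------------------------------------------------------------


@dataclass
class CodingAnnotation:
    """Per-chromosome interval set of coding-exon regions.

    Intervals are half-open 0-based internally; point queries take 1-based
    positions, matching the coordinates in call tables and VCFs.
    """

    trees: dict = field(default_factory=dict)  # chrom -> IntervalTree of (gene, strand)

    def add(self, chrom: str, start0: int, end0: int, gene: str, strand: str):
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {strand!r}")
        if end0 <= start0:
            raise ValueError(f"empty interval [{start0}, {end0})")
        self.trees.setdefault(chrom, IntervalTree())[start0:end0] = (gene, strand)

    def genes_at(self, chrom: str, pos: int) -> list:
        """All (gene, strand) pairs whose coding region covers 1-based ``pos``."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos - 1)})

    def strand_at(self, chrom: str, pos: int):
        """(gene, strand) of the unique covering gene strand, else (None, None).

        Positions covered by genes on both strands, or by none, are
        unresolvable and yield (None, None).
        """
        hits = self.genes_at(chrom, pos)
        strands = {s for _, s in hits}
        if len(strands) != 1:
            return None, None
        genes = sorted(g for g, _ in hits)
        return genes[0], strands.pop()

    def __contains__(self, key) -> bool:
        chrom, pos = key
        return bool(self.genes_at(chrom, pos))

    def n_intervals(self) -> int:
        return sum(len(t) for t in self.trees.values())


def _read_bed6(path) -> CodingAnnotation:
    ann = CodingAnnotation()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line.strip())
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED line has no strand column (6 columns required)"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            ann.add(chrom, int(start), int(end), name, strand)
    return ann


def _read_gtf(path) -> CodingAnnotation:
    """GTF/GFF reader via gffutils; uses CDS features, falling back to exon."""
    import gffutils.iterators

    features = list(gffutils.iterators.DataIterator(str(path)))
    types = {f.featuretype for f in features}
    wanted = "CDS" if "CDS" in types else "exon"
    ann = CodingAnnotation()
    for f in features:
        if f.featuretype != wanted:
            continue
        if f.strand not in ("+", "-"):
            raise FormatError(f"{path}: {wanted} feature at {f.seqid}:{f.start} lacks a strand")
        names = f.attributes.get("gene_name") or f.attributes.get("gene_id") or ["?"]
        # GTF start/end are 1-based inclusive -> half-open 0-based
        ann.add(f.seqid, f.start - 1, f.end, names[0], f.strand)
    return ann


def read_annotation(path) -> CodingAnnotation:
    """Load coding regions from a GTF/GFF (1-based inclusive) or BED6
    (0-based half-open) file, normalising to one internal convention."""
    name = str(path)
    base = name[:-3] if name.endswith(".gz") else name
    if base.endswith(".bed"):
        return _read_bed6(path)
    if base.endswith((".gtf", ".gff", ".gff3")):
        return _read_gtf(path)
    raise FormatError(f"{path}: unknown annotation format (expected .bed/.gtf/.gff[3])")


def write_gtf(ann: CodingAnnotation, path, feature: str = "CDS") -> None:
    with open(path, "wt") as fh:
        for chrom in sorted(ann.trees):
            for iv in sorted(ann.trees[chrom]):
                gene, strand = iv.data
                attrs = f'gene_id "{gene}"; gene_name "{gene}";'
                fh.write(
                    f"{chrom}\teditdiff\t{feature}\t{iv.begin + 1}\t{iv.end}\t.\t{strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = [
    "gene", "chrom", "position",
    "edited_in_control", "edited_in_case", "fisher_p", "p_adj",
]


def _sig3(p: float) -> str:
    return f"{p:.2e}"


def write_site_table(records: Sequence, path) -> None:
    """Write differential-editing records as a TSV, one row per site.

    Counts are formatted ``k/n``, p-values in scientific notation with
    3 significant digits; rows are sorted by adjusted p ascending, ties
    broken by raw p, then by (chrom, position).
    """
    ordered = sorted(
        records, key=lambda r: (r.p_adjusted, r.p_fisher, r.chrom, r.position)
    )
    with open(path, "wt") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for r in ordered:
            fh.write(
                f"{r.gene}\t{r.chrom}\t{r.position}\t"
                f"{r.k_control}/{r.n_control}\t{r.k_case}/{r.n_case}\t"
                f"{_sig3(r.p_fisher)}\t{_sig3(r.p_adjusted)}\n"
            )


def read_site_table(path) -> list:
    """Read back a differential-editing table written by :func:`write_site_table`."""
    from .diff_stats import ContingencyRecord

    records = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SITE_TABLE_COLUMNS:
            raise FormatError(f"{path}: unexpected site-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(SITE_TABLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(SITE_TABLE_COLUMNS)} columns")
            kc, nc = f[3].split("/")
            kp, np_ = f[4].split("/")
            records.append(
                ContingencyRecord(
                    gene=f[0], chrom=f[1], position=int(f[2]),
                    k_control=int(kc), n_control=int(nc),
                    k_case=int(kp), n_case=int(np_),
                    p_fisher=float(f[5]), p_adjusted=float(f[6]),
                )
            )
    return records


CALL_TABLE_COLUMNS = [
    "chrom", "position", "strand", "ref", "A", "C", "G", "T",
    "coverage", "mean_quality", "substitutions", "frequency",
]


def write_call_table(calls: Sequence, path) -> None:
    """Per-sample candidate-site table: base distribution, strand,
    substitution list and variation frequency for every called position."""
    with open(path, "wt") as fh:
        fh.write("\t".join(CALL_TABLE_COLUMNS) + "\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.position)):
            d = c.distribution
            subs = ",".join(c.substitutions)
            fh.write(
                f"{c.chrom}\t{c.position}\t{c.strand}\t{c.reference_base}\t"
                f"{d.a}\t{d.c}\t{d.g}\t{d.t}\t{d.coverage}\t"
                f"{d.mean_quality:.2f}\t{subs}\t{c.frequency:.6g}\n"
            )


def read_call_table(path) -> list:
    from .site_caller import BaseDistribution, SiteCall

    calls = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALL_TABLE_COLUMNS:
            raise FormatError(f"{path}: unexpected call-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            a, c_, g, t = (int(x) for x in f[4:8])
            dist = BaseDistribution(a=a, c=c_, g=g, t=t,
                                    quality_sum=float(f[9]) * (a + c_ + g + t))
            calls.append(
                SiteCall(
                    chrom=f[0], position=int(f[1]), strand=f[2],
                    reference_base=f[3], distribution=dist,
                    substitutions=f[10].split(",") if f[10] else [],
                    frequency=float(f[11]),
                    is_a_to_i=None,  # recomputed below
                )
            )
    out = []
    for c in calls:
        from .site_caller import _classify_a_to_i

        out.append(c.replace(is_a_to_i=_classify_a_to_i(c.strand, c.substitutions)))
    return out
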