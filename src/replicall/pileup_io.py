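"""Alignment and pileup I/O.

Reads target regions (BED), builds per-site allele observations from
coordinate-sorted BAMs, parses/writes a plain tab-separated pileup dialect
for desk-scale work, and writes scored calls as VCF 4.2.

Coordinate conventions: BED is 0-based half-open; the pileup table, all
in-memory positions, and VCF output are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "BASES",
    "SUBSTITUTION_TYPES",
    "TargetRegion",
    "SiteObservation",
    "PileupSeries",
    "ReplicateSet",
    "normalize_substitution",
    "read_targets",
    "target_length",
    "build_pileup",
    "read_pileup_table",
    "write_pileup_table",
    "write_vcf",
]

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six strand-collapsed substitution classes. Any (ref, alt) pair with
#: ref in {G, T} is reported as its reverse complement, e.g. G>A -> C>T.
SUBSTITUTION_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

PILEUP_HEADER = "chrom\tpos\tref\tdepth\talt\talt_count\talt_quals"


def normalize_substitution(ref: str, alt: str) -> str:
    """Collapse an ordered (ref, alt) base pair onto one of the six
    substitution classes rooted at A or C.

    >>> normalize_substitution("G", "A")
    'C>T'
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"non-ACGT substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref in ("G", "T"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass(frozen=True, order=True)
class TargetRegion:
    """Half-open genomic interval [start, end) on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def positions(self) -> Iterator[int]:
        """Yield the 1-based positions covered by the region."""
        return iter(range(self.start + 1, self.end + 1))


def read_targets(bed_path: str) -> list[TargetRegion]:
    """Load a BED file, returning sorted, merged target regions.

    Overlapping or book-ended regions are merged. Malformed lines raise a
    ``ValueError`` naming the offending line number.
    """
    raw: list[TargetRegion] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{bed_path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                region = TargetRegion(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: {exc}") from exc
            raw.append(region)
    return merge_regions(raw)


def merge_regions(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Sort regions and merge any that overlap or are adjacent."""
    merged: list[TargetRegion] = []
    for region in sorted(regions):
        if merged and merged[-1].chrom == region.chrom and region.start <= merged[-1].end:
            last = merged.pop()
            region = TargetRegion(last.chrom, last.start, max(last.end, region.end))
        merged.append(region)
    return merged


def target_length(regions: Iterable[TargetRegion]) -> int:
    return sum(len(r) for r in regions)


@dataclass
class SiteObservation:
    """Per-position, per-replicate allele counts with alt base qualities.

    ``depth`` counts qualifying reads (n); ``alt_counts`` maps each observed
    non-reference allele to its supporting read count (b); ``alt_quals`` maps
    it to the Phred base qualities of those reads (q_l). Optional per-strand
    fields back the strand-bias post-filter and are populated only by the
    BAM reader.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    depth: int
    alt_counts: dict[str, int] = field(default_factory=dict)
    alt_quals: dict[str, list[int]] = field(default_factory=dict)
    ref_fwd: Optional[int] = None
    alt_fwd: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if sum(self.alt_counts.values()) > self.depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt reads exceed depth {self.depth}"
            )
        for allele, count in self.alt_counts.items():
            quals = self.alt_quals.get(allele, [])
            if len(quals) != count:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: {allele} has {count} reads "
                    f"but {len(quals)} qualities"
                )
            if any(q < 0 for q in quals):
                raise ValueError(f"{self.chrom}:{self.pos}: negative base quality")

    def vaf(self, alt: str) -> float:
        """Raw VAF x = b/n for ``alt`` (0.0 at zero depth)."""
        if self.depth == 0:
            return 0.0
        return self.alt_counts.get(alt, 0) / self.depth

    def modal_alt(self) -> Optional[str]:
        """The most-supported alt allele (lexicographic tie-break)."""
        if not self.alt_counts:
            return None
        return min(self.alt_counts, key=lambda a: (-self.alt_counts[a], a))


class PileupSeries:
    """An ordered collection of SiteObservations over a target.

    Positions absent from the series are reference-only: ``get`` synthesizes
    an empty observation with ``uniform_depth`` reads (or zero coverage when
    no uniform depth is known), so sparse storage of alt-bearing sites is
    equivalent to a dense pileup.
    """

    def __init__(
        self,
        sites: Optional[Iterable[SiteObservation]] = None,
        regions: Optional[list[TargetRegion]] = None,
        uniform_depth: Optional[int] = None,
        name: str = "",
    ) -> None:
        self.sites: dict[tuple[str, int], SiteObservation] = {}
        self.regions = regions
        self.uniform_depth = uniform_depth
        self.name = name
        for site in sites or ():
            self.add(site)

    def add(self, site: SiteObservation) -> None:
        self.sites[(site.chrom, site.pos)] = site

    def get(self, chrom: str, pos: int) -> SiteObservation:
        site = self.sites.get((chrom, pos))
        if site is None:
            site = SiteObservation(chrom, pos, "N", self.uniform_depth or 0)
        return site

    def positions(self) -> list[tuple[str, int]]:
        return sorted(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[SiteObservation]:
        for key in self.positions():
            yield self.sites[key]


@dataclass
class ReplicateSet:
    """k >= 1 per-replicate pileup series over identical targets, plus an
    optional matched control used for germline masking."""

    replicates: list[PileupSeries]
    control: Optional[PileupSeries] = None
    regions: Optional[list[TargetRegion]] = None

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a ReplicateSet needs at least one replicate")

    @property
    def k(self) -> int:
        return len(self.replicates)

    def target_bp(self) -> int:
        if self.regions is not None:
            return target_length(self.regions)
        positions = set()
        for rep in self.replicates:
            positions.update(rep.sites)
        return len(positions)

    def candidate_positions(self) -> list[tuple[str, int]]:
        """Positions carrying at least one alt read in any replicate."""
        found = set()
        for rep in self.replicates:
            for key, site in rep.sites.items():
                if site.alt_counts:
                    found.add(key)
        return sorted(found)


# ---------------------------------------------------------------------------
# BAM pileup
# ---------------------------------------------------------------------------

def build_pileup(
    bam_path: str,
    ref_path: str,
    regions: list[TargetRegion],
    min_bq: int = 20,
    min_mq: int = 30,
    keep_duplicates: bool = False,
    name: str = "",
) -> PileupSeries:
    """Pile up a coordinate-sorted, indexed BAM over ``regions``.

    Reads below ``min_mq``, duplicate-flagged (unless ``keep_duplicates``,
    appropriate for amplicon libraries), secondary and supplementary reads
    are excluded. Bases below ``min_bq`` are excluded from both depth and
    alt counts. Overlapping mates are counted once, keeping the
    higher-quality base so one template molecule contributes one observation.
    """
    import pysam

    if min_bq < 0 or min_mq < 0:
        raise ValueError("quality thresholds must be non-negative")

    with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(ref_path) as fasta:
        try:
            bam.check_index()
        except (AttributeError, ValueError) as exc:
            raise FileNotFoundError(
                f"{bam_path} has no index; run 'samtools index' first"
            ) from exc
        series = PileupSeries(regions=regions, name=name or bam_path)
        for region in regions:
            if region.chrom not in fasta.references:
                raise KeyError(
                    f"chromosome {region.chrom!r} absent from reference {ref_path}"
                )
            refseq = fasta.fetch(region.chrom, region.start, region.end).upper()
            # (0-based pos) -> {query_name: (base, qual, is_forward)}
            columns: dict[int, dict[str, tuple[str, int, bool]]] = {}
            for read in bam.fetch(region.chrom, region.start, region.end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality < min_mq
                    or (read.is_duplicate and not keep_duplicates)
                    or read.query_sequence is None
                ):
                    continue
                quals = read.query_qualities
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    if rpos < region.start or rpos >= region.end:
                        continue
                    base = read.query_sequence[qpos].upper()
                    qual = 0 if quals is None else quals[qpos]
                    if qual < min_bq or base not in BASES:
                        continue
                    column = columns.setdefault(rpos, {})
                    prev = column.get(read.query_name)
                    if prev is None or qual > prev[1]:
                        column[read.query_name] = (base, qual, not read.is_reverse)
            for rpos, column in columns.items():
                ref_base = refseq[rpos - region.start]
                if ref_base not in BASES:
                    continue
                alt_counts: dict[str, int] = {}
                alt_quals: dict[str, list[int]] = {}
                alt_fwd: dict[str, int] = {}
                ref_fwd = 0
                depth = 0
                for base, qual, fwd in column.values():
                    depth += 1
                    if base == ref_base:
                        ref_fwd += int(fwd)
                    else:
                        alt_counts[base] = alt_counts.get(base, 0) + 1
                        alt_quals.setdefault(base, []).append(qual)
                        alt_fwd[base] = alt_fwd.get(base, 0) + int(fwd)
                series.add(
                    SiteObservation(
                        region.chrom,
                        rpos + 1,
                        ref_base,
                        depth,
                        alt_counts,
                        alt_quals,
                        ref_fwd=ref_fwd,
                        alt_fwd={a: alt_fwd.get(a, 0) for a in alt_counts},
                    )
                )
    return series


# ---------------------------------------------------------------------------
# Pileup table dialect
# ---------------------------------------------------------------------------
# Tab-separated, one row per (site, alt allele):
#   chrom  pos  ref  depth  alt  alt_count  alt_quals
# Reference-only sites use alt='.', alt_count=0 and an empty quality list.
# '##key=value' comment lines before the header carry series metadata
# (target regions, uniform depth) and round-trip byte-identically.


def read_pileup_table(tsv_path: str) -> PileupSeries:
    """Parse the pileup dialect into a :class:`PileupSeries`."""
    series = PileupSeries(name=tsv_path)
    pending: dict[tuple[str, int], SiteObservation] = {}
    with open(tsv_path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                if key == "uniform_depth":
                    series.uniform_depth = int(value)
                elif key == "target":
                    chrom, _, span = value.partition(":")
                    start, _, end = span.partition("-")
                    region = TargetRegion(chrom, int(start), int(end))
                    series.regions = (series.regions or []) + [region]
                continue
            if not header_seen:
                if line != PILEUP_HEADER:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: bad header; expected "
                        f"{PILEUP_HEADER!r}"
                    )
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{tsv_path}:{lineno}: expected 7 columns")
            chrom, pos_s, ref, depth_s, alt, count_s, quals_s = fields
            if ref not in BASES:
                raise ValueError(f"{tsv_path}:{lineno}: non-ACGT ref {ref!r}")
            pos, depth, count = int(pos_s), int(depth_s), int(count_s)
            quals = [int(q) for q in quals_s.split(",")] if quals_s else []
            key = (chrom, pos)
            site = pending.get(key)
            if site is None:
                site = SiteObservation(chrom, pos, ref, depth)
                pending[key] = site
            if site.ref != ref or site.depth != depth:
                raise ValueError(
                    f"{tsv_path}:{lineno}: inconsistent ref/depth at {chrom}:{pos}"
                )
            if alt == ".":
                if count != 0 or quals:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: reference-only row must have "
                        "alt_count 0 and no qualities"
                    )
                continue
            if alt not in BASES or alt == ref:
                raise ValueError(f"{tsv_path}:{lineno}: bad alt allele {alt!r}")
            if len(quals) != count:
                raise ValueError(
                    f"{tsv_path}:{lineno}: alt_count {count} does not match "
                    f"{len(quals)} listed qualities"
                )
            site.alt_counts[alt] = count
            site.alt_quals[alt] = quals
    for site in pending.values():
        # re-validate invariants after accumulating alleles
        SiteObservation(
            site.chrom, site.pos, site.ref, site.depth,
            site.alt_counts, site.alt_quals,
        )
        series.add(site)
    return series


def write_pileup_table(series: PileupSeries, out_path: str) -> None:
    """Write the series in the pileup dialect (deterministic ordering)."""
    with open(out_path, "w") as fh:
        fh.write(format_pileup_table(series))


def format_pileup_table(series: PileupSeries) -> str:
    buf = io.StringIO()
    for region in series.regions or ():
        buf.write(f"##target={region.chrom}:{region.start}-{region.end}\n")
    if series.uniform_depth is not None:
        buf.write(f"##uniform_depth={series.uniform_depth}\n")
    buf.write(PILEUP_HEADER + "\n")
    for site in series:
        if not site.alt_counts:
            buf.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.depth}\t.\t0\t\n"
            )
            continue
        for alt in sorted(site.alt_counts):
            quals = ",".join(str(q) for q in site.alt_quals[alt])
            buf.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.depth}\t"
                f"{alt}\t{site.alt_counts[alt]}\t{quals}\n"
            )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_FILTER_DESCRIPTIONS = {
    "strand_bias": "Strand bias (Fisher exact p below threshold in all replicates)",
    "min_alt_reads": "Fewer alt reads than required in at least one replicate",
    "low_depth": "Depth below the configured minimum in at least one replicate",
    "triallelic": "Competing alt allele at comparable VAF in all replicates",
    "blacklist": "Within or near a user-supplied blacklist region",
}


def write_vcf(calls, out_path: str, sample_names: Optional[list[str]] = None) -> None:
    """Write scored calls as VCF 4.2.

    ``calls`` must be sorted by (chrom, pos); an unsorted input raises.
    INFO carries the joint score S, the substitution class, the mean adjusted
    VAF, and per-replicate adjusted VAFs / MOS values; FILTER carries
    post-filter outcomes.
    """
    from . import __version__

    last: Optional[tuple[str, int]] = None
    for call in calls:
        key = (call.chrom, call.pos)
        if last is not None and key < last:
            raise ValueError(f"calls not sorted by (chrom, pos) at {key}")
        last = key

    filters_used = sorted({f for call in calls for f in call.filters})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=replicall-{__version__}",
        '##INFO=<ID=S,Number=1,Type=Float,Description="Joint replicate log-odds score (natural log)">',
        '##INFO=<ID=SUB,Number=1,Type=String,Description="Strand-collapsed substitution class">',
        '##INFO=<ID=MU,Number=1,Type=Float,Description="Mean adjusted VAF over replicates">',
        '##INFO=<ID=XBE,Number=.,Type=Float,Description="Per-replicate adjusted VAF (background-error VAF)">',
        '##INFO=<ID=MOS,Number=.,Type=Float,Description="Per-replicate mismatch over-representation score">',
        '##INFO=<ID=DP,Number=.,Type=Integer,Description="Per-replicate depth">',
        '##INFO=<ID=AC,Number=.,Type=Integer,Description="Per-replicate alt read count">',
    ]
    for name in filters_used:
        desc = _VCF_FILTER_DESCRIPTIONS.get(name, "Post-filter")
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    if sample_names:
        lines.append("##replicates=" + ",".join(sample_names))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in calls:
        filt = ";".join(call.filters) if call.filters else "PASS"
        info = (
            f"S={call.s:.4f};SUB={call.substitution};MU={call.mu_hat:.6g};"
            f"XBE={','.join(f'{e.x_be:.6g}' for e in call.evidence)};"
            f"MOS={','.join(f'{e.b_be:.4f}' for e in call.evidence)};"
            f"DP={','.join(str(e.n) for e in call.evidence)};"
            f"AC={','.join(str(e.b) for e in call.evidence)}"
        )
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\t{filt}\t{info}"
        )
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
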