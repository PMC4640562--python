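"""Read and write variant-call inputs for tumor-pair clonality testing.

Two input routes produce the same in-memory records:

* a trio of single-sample VCF files (germline, tumor A, tumor B), read with
  cyvcf2 — only SNVs are kept, multiallelic records are split;
* a tab-delimited mutation table (the canonical fixture format) with one row
  per locus and per-tissue depth / alternate-read / high-quality-depth
  columns plus a dbSNP membership flag.

Both yield one :class:`LocusEvidence` per locus key (chromosome, position,
ref, alt) that carries the read evidence needed by the high-confidence
filter.  Mutation identity is allele-level: two different alternate alleles
at one position are two distinct mutations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Column order of the canonical tab-delimited mutation table.
TABLE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "germline_depth",
    "germline_alt",
    "germline_hq_depth",
    "tumor_a_depth",
    "tumor_a_alt",
    "tumor_a_hq_depth",
    "tumor_a_called",
    "tumor_b_depth",
    "tumor_b_alt",
    "tumor_b_hq_depth",
    "tumor_b_called",
    "dbsnp",
)


@dataclass(frozen=True, order=True)
class LocusKey:
    """Allele-level identity of a single-nucleotide variant (1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(
                f"position must be 1-based (>= 1), got {self.pos} at {self.chrom}"
            )
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"SNV alleles must be single bases in ACGT: {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SampleEvidence:
    """Read evidence for one tissue at one locus.

    ``hq_depth`` counts reads above the base-quality threshold (Q>20 in the
    default pipeline); when an input format cannot supply it, readers fall
    back to ``total_depth`` with a logged warning.
    """

    total_depth: int
    alt_count: int
    hq_depth: int
    called: bool
    call_quality: float | None = None

    def __post_init__(self) -> None:
        if self.total_depth < 0 or self.alt_count < 0 or self.hq_depth < 0:
            raise ValidationError("read counts must be non-negative")
        if self.alt_count > self.total_depth:
            raise ValidationError("alt_count exceeds total_depth")
        if self.hq_depth > self.total_depth:
            raise ValidationError("hq_depth exceeds total_depth")

    @property
    def alt_fraction(self) -> float:
        """Alternate allele fraction; 0 when the locus has no coverage."""
        return self.alt_count / self.total_depth if self.total_depth else 0.0


#: Evidence marker for a tissue with no record at a locus.
ABSENT = SampleEvidence(total_depth=0, alt_count=0, hq_depth=0, called=False)


@dataclass(frozen=True)
class LocusEvidence:
    """Per-locus evidence across the germline/tumorA/tumorB trio.

    ``in_dbsnp`` is an input annotation (VCF ID field, table column, or a
    user-supplied key list); it is never computed here.
    """

    key: LocusKey
    germline: SampleEvidence
    tumor_a: SampleEvidence
    tumor_b: SampleEvidence
    in_dbsnp: bool


# ---------------------------------------------------------------------------
# tab-delimited mutation table
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | os.PathLike) -> list[LocusEvidence]:
    """Read the canonical tab-delimited mutation table into evidence records.

    The header must contain every column in :data:`TABLE_COLUMNS`; extra
    columns are ignored.  An empty table (header only) is valid and yields
    an empty list.
    """
    if not os.path.exists(path):
        raise InputError(f"mutation table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mutation table {path} missing required column(s): {', '.join(missing)}")
    records: list[LocusEvidence] = []
    for row in df.itertuples(index=False):
        records.append(
            LocusEvidence(
                key=LocusKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
                germline=SampleEvidence(
                    int(row.germline_depth), int(row.germline_alt),
                    int(row.germline_hq_depth), called=False,
                ),
                tumor_a=SampleEvidence(
                    int(row.tumor_a_depth), int(row.tumor_a_alt),
                    int(row.tumor_a_hq_depth), called=bool(row.tumor_a_called),
                ),
                tumor_b=SampleEvidence(
                    int(row.tumor_b_depth), int(row.tumor_b_alt),
                    int(row.tumor_b_hq_depth), called=bool(row.tumor_b_called),
                ),
                in_dbsnp=bool(row.dbsnp),
            )
        )
    return records


def write_mutation_table(records: Iterable[LocusEvidence], path: str | os.PathLike) -> None:
    """Write evidence records as a canonical tab-delimited mutation table."""
    rows = []
    for rec in records:
        rows.append(
            {
                "chrom": rec.key.chrom,
                "pos": rec.key.pos,
                "ref": rec.key.ref,
                "alt": rec.key.alt,
                "germline_depth": rec.germline.total_depth,
                "germline_alt": rec.germline.alt_count,
                "germline_hq_depth": rec.germline.hq_depth,
                "tumor_a_depth": rec.tumor_a.total_depth,
                "tumor_a_alt": rec.tumor_a.alt_count,
                "tumor_a_hq_depth": rec.tumor_a.hq_depth,
                "tumor_a_called": int(rec.tumor_a.called),
                "tumor_b_depth": rec.tumor_b.total_depth,
                "tumor_b_alt": rec.tumor_b.alt_count,
                "tumor_b_hq_depth": rec.tumor_b.hq_depth,
                "tumor_b_called": int(rec.tumor_b.called),
                "dbsnp": int(rec.in_dbsnp),
            }
        )
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF trio
# ---------------------------------------------------------------------------

def _fmt(variant, field: str):
    """FORMAT field of the first sample, or None when absent from the header/record."""
    try:
        return variant.format(field)
    except KeyError:
        return None


def _sample_evidence_from_vcf(variant, alt_index: int, called: bool) -> SampleEvidence:
    """Build SampleEvidence from a cyvcf2 variant's first-sample fields."""
    depth = None
    dp = _fmt(variant, "DP")
    if dp is not None:
        depth = int(dp[0][0])
    elif variant.INFO.get("DP") is not None:
        depth = int(variant.INFO.get("DP"))
    ad = _fmt(variant, "AD")
    alt_count = 0
    if ad is not None:
        row = [int(x) for x in ad[0] if int(x) >= 0]
        if depth is None:
            depth = sum(row)
        if len(row) > alt_index + 1:
            alt_count = row[alt_index + 1]
    if depth is None:
        raise FormatError(
            "VCF record lacks depth fields (DP/AD): "
            f"{variant.CHROM}:{variant.POS} {variant.REF}>{','.join(variant.ALT or ['.'])}"
        )
    hq = _fmt(variant, "HQD")
    if hq is not None:
        hq_depth = int(hq[0][0])
    else:
        logger.warning(
            "no per-read quality depth (HQD) at %s:%s; using total depth",
            variant.CHROM, variant.POS,
        )
        hq_depth = depth
    alt_count = min(alt_count, depth)
    quality = float(variant.QUAL) if variant.QUAL is not None else None
    return SampleEvidence(depth, alt_count, min(hq_depth, depth), called, quality)


def _parse_single_sample_vcf(path: str | os.PathLike):
    """Yield (key, evidence, id_field, is_variant_call) for SNV records.

    Multiallelic records are split into one item per alternate allele;
    non-SNV alleles are skipped with a tallied warning.
    """
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise InputError(f"VCF not found: {path}")
    skipped = 0
    vcf = VCF(str(path))
    try:
        for variant in vcf:
            ref = variant.REF
            alts = variant.ALT or []
            gt = variant.genotypes[0][:-1] if variant.genotypes else []
            if not alts and len(ref) == 1 and ref in _BASES:
                # homozygous-reference coverage record (germline / uncalled tumor)
                yield None, variant, None, False
                continue
            for i, alt in enumerate(alts):
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    skipped += 1
                    continue
                key = LocusKey(variant.CHROM, variant.POS, ref, alt)
                is_call = (i + 1) in gt if gt else True
                yield key, variant, i, is_call
    finally:
        vcf.close()
    if skipped:
        logger.warning("%s: skipped %d non-SNV allele(s)", path, skipped)


def read_trio_vcfs(
    germline_path: str | os.PathLike,
    tumor_a_path: str | os.PathLike,
    tumor_b_path: str | os.PathLike,
    dbsnp_flag_source: str | set[LocusKey] = "vcf_id",
) -> list[LocusEvidence]:
    """Read a germline/tumorA/tumorB VCF trio into evidence records.

    One record is produced per locus key carrying a variant call in either
    tumor.  Tumor VCFs may additionally contain homozygous-reference
    coverage records (GT 0/0) giving depth at loci called only in the other
    tumor; where such a record is absent the tumor's evidence is marked
    absent (zero depth), which the high-confidence filter rejects for lack
    of coverage — likewise for loci with no germline record.

    ``dbsnp_flag_source`` is ``"vcf_id"`` (flag set when a tumor record's ID
    field is non-missing) or a set of :class:`LocusKey` to flag.
    """
    tumor_calls: dict[LocusKey, dict[str, SampleEvidence]] = {}
    tumor_cov: dict[str, dict[tuple[str, int], SampleEvidence]] = {"a": {}, "b": {}}
    dbsnp_ids: set[LocusKey] = set()

    for label, path in (("a", tumor_a_path), ("b", tumor_b_path)):
        for key, variant, alt_index, is_call in _parse_single_sample_vcf(path):
            if key is None:
                ev = _sample_evidence_from_vcf(variant, 0, called=False)
                tumor_cov[label][(variant.CHROM, variant.POS)] = ev
                continue
            ev = _sample_evidence_from_vcf(variant, alt_index, called=is_call)
            if is_call:
                tumor_calls.setdefault(key, {})[label] = ev
                if dbsnp_flag_source == "vcf_id" and variant.ID not in (None, "", "."):
                    dbsnp_ids.add(key)
            else:
                tumor_cov[label][(variant.CHROM, variant.POS)] = ev

    germline: dict[tuple[str, int], SampleEvidence] = {}
    for key, variant, alt_index, _ in _parse_single_sample_vcf(germline_path):
        ev = _sample_evidence_from_vcf(variant, alt_index or 0, called=False)
        germline[(variant.CHROM, variant.POS)] = ev

    if isinstance(dbsnp_flag_source, set):
        dbsnp_ids = dbsnp_flag_source

    records = []
    for key in sorted(tumor_calls):
        calls = tumor_calls[key]
        pos = (key.chrom, key.pos)
        ev_a = calls.get("a") or tumor_cov["a"].get(pos, ABSENT)
        ev_b = calls.get("b") or tumor_cov["b"].get(pos, ABSENT)
        records.append(
            LocusEvidence(
                key=key,
                germline=germline.get(pos, ABSENT),
                tumor_a=ev_a,
                tumor_b=ev_b,
                in_dbsnp=key in dbsnp_ids,
            )
        )
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=HQD,Number=1,Type=Integer,Description="Depth of reads with base quality > 20">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _contig_lines(records: Sequence[LocusEvidence]) -> str:
    contigs = sorted({r.key.chrom for r in records})
    return "".join(f"##contig=<ID={c}>\n" for c in contigs)


def _vcf_line(rec: LocusEvidence, ev: SampleEvidence, variant: bool) -> str:
    key = rec.key
    vid = "rs1" if rec.in_dbsnp and variant else "."
    alt = key.alt if variant else "."
    gt = "0/1" if (variant and ev.called) else "0/0"
    ad = f"{ev.total_depth - ev.alt_count},{ev.alt_count}" if variant else str(ev.total_depth)
    qual = f"{ev.call_quality:g}" if ev.call_quality is not None else "."
    return (
        f"{key.chrom}\t{key.pos}\t{vid}\t{key.ref}\t{alt}\t{qual}\t.\t.\t"
        f"GT:DP:AD:HQD\t{gt}:{ev.total_depth}:{ad}:{ev.hq_depth}\n"
    )


def write_trio_vcfs(
    records: Sequence[LocusEvidence],
    germline_path: str | os.PathLike,
    tumor_a_path: str | os.PathLike,
    tumor_b_path: str | os.PathLike,
) -> None:
    """Write evidence records as a trio of single-sample VCF files.

    The germline file carries homozygous-reference coverage records at every
    locus; each tumor file carries a 0/1 call where that tumor called the
    variant and a 0/0 coverage record otherwise, so that the trio
    round-trips through :func:`read_trio_vcfs`.
    """
    ordered = sorted(records, key=lambda r: r.key)
    contigs = _contig_lines(ordered)
    # germline rows also spell out the alternate allele (with GT 0/0) so the
    # germline alt-read count survives the round trip in AD
    specs = (
        (germline_path, "GERMLINE", lambda r: (r.germline, True)),
        (tumor_a_path, "TUMOR_A", lambda r: (r.tumor_a, True)),
        (tumor_b_path, "TUMOR_B", lambda r: (r.tumor_b, True)),
    )
    for path, sample, pick in specs:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n" + contigs +
                     _VCF_HEADER.format(sample=sample).split("\n", 1)[1])
            for rec in ordered:
                ev, variant = pick(rec)
                fh.write(_vcf_line(rec, ev, variant))


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def write_report(result, path: str | os.PathLike, format: str = "json") -> None:
    """Write a :class:`~clstest.cls_test.CLSResult` as a JSON or TSV report.

    Numeric fields are written at full precision; the ``cls_display`` /
    ``ci_display`` fields carry the rounded presentation strings.
    """
    if format not in {"json", "tsv"}:
        raise ValidationError(f"report format must be 'json' or 'tsv', got {format!r}")
    payload = result.to_dict()
    try:
        if format == "json":
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
                fh.write("\n")
        else:
            flat = _flatten(payload)
            pd.DataFrame([flat]).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise InputError(f"cannot write report to {path}: {exc}") from exc


def _flatten(d: Mapping, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        name = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, f"{name}."))
        else:
            out[name] = v
    return out


def read_report(path: str | os.PathLike) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
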