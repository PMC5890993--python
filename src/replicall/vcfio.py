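"""VCF output (and truth VCF round trip).

Variant keys use pileup tokens internally (``+SEQ`` insertions, ``-n``
deletions anchored at the preceding base); this module converts them to
VCF 4.2 anchor-base alleles on write and back on read. Deletions need
the deleted reference sequence, available from a reference mapping
(contig -> sequence, 1-based); without one, ``N`` placeholders are
written.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, TextIO

import pysam

from .calling import VariantTestResult
from .matrix import VariantClass, VariantKey

_INFO_HEADER = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Mean allele frequency across sample replicates">',
    '##INFO=<ID=P,Number=1,Type=Float,Description="Raw enrichment p-value">',
    '##INFO=<ID=ADJP,Number=1,Type=Float,Description="Benjamini-Hochberg adjusted p-value">',
    '##INFO=<ID=SBF,Number=1,Type=Float,Description="Strand bias factor (fwd AF / rev AF)">',
    '##INFO=<ID=NREP_SUP,Number=1,Type=Integer,Description="Sample replicates with >=1 supporting read">',
]
_FILTER_HEADER = [
    '##FILTER=<ID=ADJ_P,Description="Adjusted p-value above significance threshold">',
    '##FILTER=<ID=DIRECTION,Description="Sample normalized mean not above control">',
    '##FILTER=<ID=STRAND_BIAS,Description="Strand bias factor magnitude above limit">',
    '##FILTER=<ID=LOW_AF,Description="Mean allele frequency below threshold">',
    '##FILTER=<ID=NO_AF,Description="No covered sample replicate">',
]


def key_to_vcf_alleles(
    key: VariantKey, reference: Mapping[str, str] | None = None
) -> tuple[int, str, str]:
    """(POS, REF, ALT) in VCF anchor-base convention for a token key."""
    if key.vclass is VariantClass.SNV:
        return key.pos, key.ref, key.alt
    if key.vclass is VariantClass.INS:
        return key.pos, key.ref, key.ref + key.alt[1:]
    n = int(key.alt[1:])
    if reference is not None and key.contig in reference:
        seq = reference[key.contig][key.pos : key.pos + n]
    else:
        seq = "N" * n
    return key.pos, key.ref + seq, key.ref


def vcf_alleles_to_key(contig: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Invert :func:`key_to_vcf_alleles` back to the token convention."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return VariantKey(contig, pos, ref, alt, VariantClass.SNV)
    if len(alt) > len(ref) == 1 and alt.startswith(ref):
        return VariantKey(contig, pos, ref, "+" + alt[1:], VariantClass.INS)
    if len(ref) > len(alt) == 1 and ref.startswith(alt):
        return VariantKey(contig, pos, alt, f"-{len(ref) - 1}", VariantClass.DEL)
    raise ValueError(f"unsupported VCF alleles {ref}>{alt} at {contig}:{pos}")


def _fmt(x: float) -> str:
    if x != x:  # nan
        return "."
    if x == float("inf"):
        return "1e999"  # serialized as VCF has no inf literal; readers see a large float
    return f"{x:.6g}"


def write_vcf(
    results: Sequence[VariantTestResult],
    out: TextIO,
    reference: Mapping[str, str] | None = None,
    emit_all: bool = False,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write called (or, with emit_all, all tested) variants as VCF 4.2."""
    out.write("##fileformat=VCFv4.2\n")
    out.write("##source=replicall\n")
    for k, v in (meta or {}).items():
        out.write(f"##replicall_{k}={v}\n")
    contigs = sorted({r.key.contig for r in results})
    for c in contigs:
        out.write(f"##contig=<ID={c}>\n")
    for line in _INFO_HEADER + _FILTER_HEADER:
        out.write(line + "\n")
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    rows = [r for r in results if r.call or emit_all]
    rows.sort(key=lambda r: r.key.sort_key)
    for r in rows:
        pos, ref, alt = key_to_vcf_alleles(r.key, reference)
        filt = "PASS" if r.call else ";".join(r.reasons)
        sbf = r.sbf
        sbf_s = "." if sbf != sbf else (f"{sbf:.6g}" if abs(sbf) != float("inf") else ".")
        info = (
            f"AF={_fmt(r.mean_af)};P={_fmt(r.p)};ADJP={_fmt(r.adj_p)};"
            f"SBF={sbf_s};NREP_SUP={r.n_rep_support}"
        )
        out.write(f"{r.key.contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n")


def write_simple_vcf(
    records: Iterable[tuple[VariantKey, float]],
    out: TextIO,
    reference: Mapping[str, str] | None = None,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Minimal VCF of (key, AF) pairs; used for simulator truth sets."""
    recs = sorted(records, key=lambda ka: ka[0].sort_key)
    out.write("##fileformat=VCFv4.2\n")
    out.write("##source=replicall-truth\n")
    for k, v in (meta or {}).items():
        out.write(f"##replicall_{k}={v}\n")
    for c in sorted({k.contig for k, _ in recs}):
        out.write(f"##contig=<ID={c}>\n")
    out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Expected allele frequency">\n')
    out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for key, af in recs:
        pos, ref, alt = key_to_vcf_alleles(key, reference)
        out.write(f"{key.contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af:.6g}\n")


def read_vcf_keys(path: str) -> list[tuple[VariantKey, float]]:
    """Read a VCF into (token VariantKey, AF) pairs via pysam.

    AF is taken from the INFO field when present, else nan. Only PASS
    (or unfiltered) records are returned.
    """
    out: list[tuple[VariantKey, float]] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            filters = set(rec.filter.keys())
            if filters and filters != {"PASS"}:
                continue
            af = rec.info.get("AF", float("nan"))
            if isinstance(af, tuple):
                af = af[0]
            for alt in rec.alts or ():
                key = vcf_alleles_to_key(rec.contig, rec.pos, rec.ref, alt)
                out.append((key, float(af)))
    return out
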