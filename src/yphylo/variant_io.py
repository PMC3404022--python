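"""Readers and writers for the formats the pipeline touches.

VCF reading is backed by pysam; everything else is plain tab-separated text.
All writers end files with a newline and use tabs as the only delimiter.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import (
    CallState,
    FormatError,
    GenotypeMatrix,
    KnownVariantList,
    Variant,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_known_list",
    "read_sample_metadata",
    "write_sample_metadata",
    "write_variant_table",
    "read_variant_table",
]

ANCESTRAL_POLICIES = ("info-anc", "ref-is-ancestral", "control-majority")


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT"


def read_vcf(
    path: Path | str,
    ancestral_policy: str = "info-anc",
    ambiguity_threshold_reads: int = 2,
    sample_metadata: Optional[dict[str, str]] = None,
) -> GenotypeMatrix:
    """Read a haploid VCF into a :class:`GenotypeMatrix`.

    Haploid GT values ``0``/``1``/``.`` map to ancestral/derived/missing
    (orientation per ``ancestral_policy``); diploid-coded homozygous calls are
    accepted, and heterozygous calls become AMBIGUOUS. When an AD field is
    present, a call whose two allele depths both reach
    ``ambiguity_threshold_reads`` — or tie at a nonzero depth — is AMBIGUOUS
    regardless of GT.

    With policy ``info-anc`` the ancestral allele comes from the INFO ``ANC``
    key when present, falling back to REF. Policy ``control-majority`` reads
    with REF orientation; the screening stage re-derives orientation from
    control samples afterwards.

    Multi-allelic and indel records are skipped with a logged warning; the
    per-reason skip counts are attached to the returned matrix as the
    ``skipped`` attribute. A record pysam cannot parse raises
    :class:`FormatError` naming the record number.
    """
    if ancestral_policy not in ANCESTRAL_POLICIES:
        raise FormatError(f"unknown ancestral policy {ancestral_policy!r}")

    skipped = {"multiallelic": 0, "indel": 0, "bad_anc": 0}
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    ad_columns: list[np.ndarray] = []
    have_ad = False

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        record_no = 0
        iterator = vcf.fetch() if vcf.index is not None else iter(vcf)
        while True:
            record_no += 1
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # malformed record inside pysam
                raise FormatError(
                    f"{path}: cannot parse VCF record {record_no}: {exc}"
                ) from exc

            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                logger.warning(
                    "%s: skipping record %d at %s:%d (%d ALT alleles)",
                    path, record_no, rec.chrom, rec.pos, len(alts),
                )
                continue
            ref, alt = rec.ref, alts[0]
            if not _is_snv(ref, alt):
                skipped["indel"] += 1
                logger.warning(
                    "%s: skipping non-SNV record %d at %s:%d (%s>%s)",
                    path, record_no, rec.chrom, rec.pos, ref, alt,
                )
                continue

            anc = ref
            if ancestral_policy == "info-anc":
                info_anc = rec.info.get("ANC")
                if info_anc is not None:
                    info_anc = str(info_anc)
                    if info_anc not in (ref, alt):
                        skipped["bad_anc"] += 1
                        logger.warning(
                            "%s: skipping record %d at %s:%d "
                            "(ANC=%s matches neither allele)",
                            path, record_no, rec.chrom, rec.pos, info_anc,
                        )
                        continue
                    anc = info_anc
            der = alt if anc == ref else ref
            derived_index = 1 if anc == ref else 0

            name = rec.id if rec.id and rec.id != "." else None
            rs_id = name if name and name.startswith("rs") else None
            variants.append(
                Variant(
                    contig=rec.chrom,
                    position=rec.pos,
                    ancestral_allele=anc,
                    derived_allele=der,
                    name=name,
                    rs_id=rs_id,
                )
            )

            col = np.empty(len(samples), dtype=np.int8)
            ad_col = np.zeros((len(samples), 2), dtype=np.int32)
            for i, s in enumerate(samples):
                fmt = rec.samples[s]
                gt = fmt.get("GT")
                alleles = tuple(a for a in (gt or ()) if a is not None)
                if not alleles:
                    state = CallState.MISSING
                elif len(set(alleles)) > 1:
                    state = CallState.AMBIGUOUS
                else:
                    state = (
                        CallState.DERIVED
                        if alleles[0] == derived_index
                        else CallState.ANCESTRAL
                    )

                ad = fmt.get("AD")
                if ad is not None and len(ad) == 2 and None not in ad:
                    anc_reads = int(ad[0] if derived_index == 1 else ad[1])
                    der_reads = int(ad[1] if derived_index == 1 else ad[0])
                    ad_col[i] = (anc_reads, der_reads)
                    have_ad = True
                    thr = ambiguity_threshold_reads
                    if (anc_reads >= thr and der_reads >= thr) or (
                        anc_reads == der_reads > 0
                    ):
                        state = CallState.AMBIGUOUS
                col[i] = state
            columns.append(col)
            ad_columns.append(ad_col)

    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    ad = np.stack(ad_columns, axis=1) if (ad_columns and have_ad) else None
    matrix = GenotypeMatrix(
        samples, variants, calls, populations=sample_metadata, ad=ad
    )
    matrix.skipped = skipped  # type: ignore[attr-defined]
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: Path | str) -> None:
    """Write a haploid VCF 4.2 with INFO ANC and a per-call AD field.

    GT is ``0``/``1``/``.``; AMBIGUOUS cells carry their majority allele (or
    ``.`` on a tie) in GT and are recoverable from AD. REF is the ancestral
    allele. Output is deterministic: records sorted by (contig, position).
    """
    order = sorted(range(matrix.n_variants), key=lambda j: matrix.variants[j].key)
    default_thr = 2

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({v.contig for v in matrix.variants}) or ["chrY"]
        for contig in contigs:
            fh.write(f"##contig=<ID={contig},length=60000001>\n")
        fh.write(
            '##INFO=<ID=ANC,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth per allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in order:
            v = matrix.variants[j]
            fields = [
                v.contig,
                str(v.position),
                v.name or ".",
                v.ancestral_allele,
                v.derived_allele,
                ".",
                "PASS",
                f"ANC={v.ancestral_allele}",
                "GT:AD",
            ]
            for i in range(matrix.n_samples):
                state = CallState(matrix.calls[i, j])
                if matrix.ad is not None:
                    anc_reads, der_reads = (
                        int(matrix.ad[i, j, 0]),
                        int(matrix.ad[i, j, 1]),
                    )
                else:
                    anc_reads, der_reads = {
                        CallState.ANCESTRAL: (1, 0),
                        CallState.DERIVED: (0, 1),
                        CallState.MISSING: (0, 0),
                        CallState.AMBIGUOUS: (default_thr, default_thr),
                    }[state]
                if state == CallState.MISSING:
                    gt = "."
                elif state == CallState.ANCESTRAL:
                    gt = "0"
                elif state == CallState.DERIVED:
                    gt = "1"
                else:  # AMBIGUOUS: majority allele, "." on a tie
                    if anc_reads > der_reads:
                        gt = "0"
                    elif der_reads > anc_reads:
                        gt = "1"
                    else:
                        gt = "."
                fields.append(f"{gt}:{anc_reads},{der_reads}")
            fh.write("\t".join(fields) + "\n")


def read_known_list(path: Path | str) -> KnownVariantList:
    """Read a known-variant table (columns name/contig/position/derived).

    Duplicate (contig, position, derived) keys are collapsed to the first
    occurrence with a logged warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return KnownVariantList()
    required = {"name", "contig", "position", "derived"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    entries: dict[tuple[str, int, str], str] = {}
    for row in df.itertuples(index=False):
        key = (str(row.contig), int(row.position), str(row.derived))
        if key in entries:
            logger.warning(
                "%s: duplicate known-variant key %s (keeping %r, dropping %r)",
                path, key, entries[key], row.name,
            )
            continue
        entries[key] = str(row.name)
    return KnownVariantList(entries)


def read_sample_metadata(path: Path | str) -> dict[str, str]:
    """Read the sidecar sample metadata table (sample_id, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "population"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["sample_id"], df["population"]))


def write_sample_metadata(
    samples: Sequence[str], populations: dict[str, str], path: Path | str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in samples:
            fh.write(f"{s}\t{populations.get(s, 'NA')}\n")


_TABLE_COLUMNS = [
    "name",
    "contig",
    "position",
    "ancestral",
    "derived",
    "known",
    "outcome",
    "derived_cases",
    "observed_controls",
    "ambiguous_calls",
    "conflict_partners",
    "branch",
    "notes",
]


def write_variant_table(
    variants: Sequence[Variant],
    filter_report,
    path: Path | str,
    branch_assignment: Optional[dict[tuple[str, int], str]] = None,
) -> None:
    """Write the per-variant outcome table (stable column order, re-readable).

    ``filter_report`` must cover every variant; ``branch_assignment`` maps
    variant keys to tree-branch labels for retained variants.
    """
    branch_assignment = branch_assignment or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for v in variants:
            rec = filter_report.record(v.key)
            row = [
                v.name or "",
                v.contig,
                str(v.position),
                v.ancestral_allele,
                v.derived_allele,
                "known" if v.known else "novel",
                rec.outcome.name,
                str(rec.derived_cases),
                str(rec.observed_controls),
                str(rec.ambiguous_calls),
                ",".join(rec.conflict_partners),
                branch_assignment.get(v.key, ""),
                ";".join(rec.notes),
            ]
            fh.write("\t".join(row) + "\n")


def read_variant_table(path: Path | str) -> pd.DataFrame:
    """Read a table written by :func:`write_variant_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    return df
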