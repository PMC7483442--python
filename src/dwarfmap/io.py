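"""Readers and writers: VCF with per-bulk allele depths, TSV, BED, JSON, FASTA.

Internal coordinates are 1-based inclusive throughout (VCF convention); BED
exports are converted to 0-based half-open at the boundary only.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bsa_scan import Region
from .splice_effect import GeneModel, IsoformResult, Variant
from .synthetic_cross import SITE_COLUMNS


class VcfParseError(ValueError):
    pass


def read_bulk_vcf(path: str | Path, sample_d: str, sample_v: str,
                  split_multiallelic: bool = False) -> pd.DataFrame:
    """SiteCounts table from a VCF with AD FORMAT fields for two samples.

    Biallelic records yield one row each; multi-allelic records are split
    into one row per ALT (ref depth shared) when ``split_multiallelic``,
    else skipped.  ``variant_kind`` is SNP when REF and ALT have equal
    length, InDel otherwise.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for name in (sample_d, sample_v):
        if name not in samples:
            raise VcfParseError(f"sample {name!r} not in VCF (available: {samples})")
    rows = []
    for rec in vf:
        if rec.alts is None:
            continue
        n_alts = len(rec.alts)
        if n_alts > 1 and not split_multiallelic:
            continue
        for sample in (sample_d, sample_v):
            if rec.samples[sample].get("AD") is None:
                raise VcfParseError(f"missing AD for {sample} at {rec.chrom}:{rec.pos}")
        ad_d = rec.samples[sample_d]["AD"]
        ad_v = rec.samples[sample_v]["AD"]
        for i, alt in enumerate(rec.alts, start=1):
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos,
                "n_ref_D": int(ad_d[0]), "n_alt_D": int(ad_d[i]),
                "n_ref_V": int(ad_v[0]), "n_alt_V": int(ad_v[i]),
                "variant_kind": "SNP" if len(rec.ref) == len(alt) else "InDel",
            })
    vf.close()
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_bulk_vcf(counts: pd.DataFrame, path: str | Path, sample_d: str = "D_bulk",
                   sample_v: str = "V_bulk", chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a SiteCounts table as a two-sample VCF v4.2 with AD fields.

    The simulator models read counts rather than sequence, so synthetic
    alleles are emitted: A>T for SNPs and A>AT for InDels (the length
    difference preserves ``variant_kind`` on round trip).
    """
    header = pysam.VariantHeader()
    lengths = dict(chrom_lengths or {})
    for chrom in pd.unique(counts["chrom"]):
        grp_max = int(counts.loc[counts["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=lengths.get(chrom, grp_max + 1))
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("GT", "1", "String", "Genotype")
    header.add_sample(sample_d)
    header.add_sample(sample_v)
    out = pysam.VariantFile(str(path), "w", header=header)
    for row in counts.itertuples(index=False):
        ref, alt = ("A", "T") if row.variant_kind == "SNP" else ("A", "AT")
        rec = out.new_record(contig=str(row.chrom), start=int(row.pos) - 1,
                             alleles=(ref, alt))
        rec.samples[sample_d]["AD"] = (int(row.n_ref_D), int(row.n_alt_D))
        rec.samples[sample_v]["AD"] = (int(row.n_ref_V), int(row.n_alt_V))
        out.write(rec)
    out.close()


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV writer with deterministic column order (round-trips via read_table)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions_bed(regions: list[Region], path: str | Path) -> None:
    """Called regions as BED (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_regions_bed(path: str | Path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            regions.append((chrom, int(start) + 1, int(end)))
    return regions


def write_gene_model_json(model: GeneModel, variant: Variant | None, path: str | Path) -> None:
    payload = {
        "sequence": model.sequence,
        "exons": [list(e) for e in model.exons],
        "strand": model.strand,
        "domains": {k: list(v) for k, v in model.domain_intervals.items()},
    }
    if variant is not None:
        payload["variant"] = {"pos": variant.pos, "ref": variant.ref_base,
                              "alt": variant.alt_base}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_gene_model_json(path: str | Path) -> tuple[GeneModel, Variant | None]:
    payload = json.loads(Path(path).read_text())
    model = GeneModel(
        sequence=payload["sequence"],
        exons=[tuple(e) for e in payload["exons"]],
        strand=payload.get("strand", "+"),
        domain_intervals={k: tuple(v) for k, v in payload.get("domains", {}).items()},
    )
    variant = None
    if "variant" in payload:
        v = payload["variant"]
        variant = Variant(pos=int(v["pos"]), ref_base=v["ref"], alt_base=v["alt"])
    return model, variant


def write_protein_fasta(isoforms: list[IsoformResult], path: str | Path,
                        gene_name: str = "gene") -> None:
    records = [
        SeqRecord(Seq(iso.protein), id=f"{gene_name}|{iso.label}",
                  description=f"{iso.protein_length} aa")
        for iso in isoforms
    ]
    SeqIO.write(records, str(path), "fasta")


def isoform_report(isoforms: list[IsoformResult]) -> pd.DataFrame:
    """Tidy isoform report (one row per isoform, domains flattened)."""
    rows = []
    for iso in isoforms:
        row = {
            "label": iso.label,
            "cds_length": len(iso.transcript),
            "cds_delta": iso.cds_delta,
            "stop_start": iso.stop_codon_span[0] if iso.stop_codon_span else None,
            "stop_end": iso.stop_codon_span[1] if iso.stop_codon_span else None,
            "protein_length": iso.protein_length,
        }
        for name, status in iso.domains_retained.items():
            row[f"domain:{name}"] = status
        rows.append(row)
    return pd.DataFrame(rows)
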