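"""Readers and writers for the cohort's on-disk formats.

A cohort directory contains:

* ``cohort.yaml``    — patients, samples, materials, collection dates,
  inclusion criteria, prior-testing registry, hereditary-panel gene list
* ``variants.tsv``   — one row per variant call (dialect below)
* ``cnv.tsv``        — gene-level fold-changes per sample
* ``msi.tsv``        — microsatellite locus repeat-length counts (optional)

Variant TSV columns: sample_id, chrom, pos, ref, alt, gene, hgvs_c,
hgvs_p, variant_class, consequence, vaf, depth, cosmic_count,
db_gnomad_exome, db_gnomad_genome, db_1000g, and the optional
pathogenicity / repeat_context columns.

A minimal single-sample VCF is also accepted for variant ingestion; the
INFO/FORMAT key map is documented in :data:`VCF_KEY_MAP`.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    DB_NAMES,
    Cohort,
    CopyNumberCall,
    FormatError,
    KnowledgeBase,
    MsiLocusProfile,
    PatientRecord,
    SampleRecord,
    VariantCall,
    VariantKey,
)

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_c", "hgvs_p",
    "variant_class", "consequence", "vaf", "depth", "cosmic_count",
    "db_gnomad_exome", "db_gnomad_genome", "db_1000g",
]
OPTIONAL_COLUMNS = ["pathogenicity", "repeat_context"]

#: How VAF/depth/annotation fields are pulled out of a minimal VCF.
VCF_KEY_MAP = {
    "vaf": ("FORMAT:AF", "INFO:VAF"),
    "depth": ("FORMAT:DP", "INFO:DP"),
    "gene": "INFO:GENE",
    "hgvs_p": "INFO:HGVSP",
    "hgvs_c": "INFO:HGVSC",
    "consequence": "INFO:CSQ",
    "cosmic_count": "INFO:COSMIC",
    "db_gnomad_exome": "INFO:DB_GE",
    "db_gnomad_genome": "INFO:DB_GG",
    "db_1000g": "INFO:DB_KG",
}


def _call_to_row(call: VariantCall) -> dict:
    return {
        "sample_id": call.sample_id,
        "chrom": call.key.chrom,
        "pos": call.key.pos,
        "ref": call.key.ref,
        "alt": call.key.alt,
        "gene": call.gene,
        "hgvs_c": call.hgvs_c,
        "hgvs_p": call.hgvs_p,
        "variant_class": call.variant_class,
        "consequence": call.consequence,
        "vaf": repr(call.vaf),
        "depth": call.depth,
        "cosmic_count": call.cosmic_count,
        **{n: call.db_counts[n] for n in DB_NAMES},
        "pathogenicity": call.pathogenicity,
        "repeat_context": int(call.repeat_context),
    }


def _opt_str(value, default: str) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    return str(value) or default


def _row_to_call(row: dict, lineno: int) -> VariantCall:
    try:
        vaf = float(row["vaf"])
        if not 0.0 <= vaf <= 1.0:
            raise FormatError(f"VAF outside [0,1]: {vaf}")
        return VariantCall(
            key=VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"])),
            gene=str(row["gene"]),
            vaf=vaf,
            depth=int(row["depth"]),
            sample_id=str(row["sample_id"]),
            hgvs_p="" if pd.isna(row["hgvs_p"]) else str(row["hgvs_p"]),
            hgvs_c="" if pd.isna(row["hgvs_c"]) else str(row["hgvs_c"]),
            variant_class=str(row["variant_class"]),
            consequence=str(row["consequence"]),
            cosmic_count=int(row["cosmic_count"]),
            db_counts={n: int(row[n]) for n in DB_NAMES},
            pathogenicity=_opt_str(row.get("pathogenicity"), "none"),
            repeat_context=bool(int(float(_opt_str(row.get("repeat_context"), "0")))),
        )
    except FormatError as e:
        raise FormatError(f"row {lineno}: {e}") from None
    except (KeyError, ValueError, TypeError) as e:
        raise FormatError(f"row {lineno}: {e}") from None


def read_variant_table(path: str | Path, material: str | None = None) -> list[VariantCall]:
    """Read variant calls from the documented TSV dialect or a minimal VCF.

    Rows are parsed strictly; a malformed row raises a
    :class:`FormatError` naming the offending line.  ``material`` is
    accepted for interface symmetry (the material lives on the sample
    record, not the call).
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    return [_row_to_call(row, i + 2) for i, row in enumerate(df.to_dict("records"))]


def _read_vcf(path: Path) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    vcf = VCF(str(path))
    sample_id = vcf.samples[0] if vcf.samples else path.stem
    for rec in vcf:
        for alt in rec.ALT:
            vaf = None
            if vcf.samples:
                try:
                    af = rec.format("AF")
                    if af is not None:
                        vaf = float(af[0][0])
                except KeyError:
                    pass
            if vaf is None:
                v = rec.INFO.get("VAF")
                vaf = float(v) if v is not None else None
            if vaf is None:
                raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AF/VAF")
            depth = rec.INFO.get("DP")
            if depth is None and vcf.samples:
                dp = rec.format("DP")
                depth = int(dp[0][0]) if dp is not None else 0
            calls.append(VariantCall(
                key=VariantKey(rec.CHROM, rec.POS, rec.REF, alt),
                gene=str(rec.INFO.get("GENE", "")),
                vaf=vaf,
                depth=int(depth or 0),
                sample_id=sample_id,
                hgvs_p=str(rec.INFO.get("HGVSP", "") or ""),
                hgvs_c=str(rec.INFO.get("HGVSC", "") or ""),
                consequence=str(rec.INFO.get("CSQ", "nonsynonymous")),
                cosmic_count=int(rec.INFO.get("COSMIC", 0) or 0),
                db_counts={
                    "db_gnomad_exome": int(rec.INFO.get("DB_GE", 0) or 0),
                    "db_gnomad_genome": int(rec.INFO.get("DB_GG", 0) or 0),
                    "db_1000g": int(rec.INFO.get("DB_KG", 0) or 0),
                },
            ))
    return calls


def write_variant_table(calls: list[VariantCall], path: str | Path) -> None:
    rows = [_call_to_row(c) for c in calls]
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS + OPTIONAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Knowledge base


def read_knowledge_base(path: str | Path) -> KnowledgeBase:
    """KB TSV: gene, descriptor, oncokb_level, amp_tier.  Duplicate
    (gene, descriptor) pairs and unknown level/tier tokens are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["gene", "descriptor", "oncokb_level", "amp_tier"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    kb = KnowledgeBase()
    for i, row in enumerate(df.to_dict("records")):
        try:
            kb.add(row["gene"], row["descriptor"], row["oncokb_level"], row["amp_tier"])
        except FormatError as e:
            raise FormatError(f"{path} row {i + 2}: {e}") from None
    return kb


def write_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    rows = [
        {"gene": g, "descriptor": d, "oncokb_level": e.oncokb_level, "amp_tier": e.amp_tier}
        for (g, d), e in sorted(kb.entries.items())
    ]
    pd.DataFrame(rows, columns=["gene", "descriptor", "oncokb_level", "amp_tier"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# CNV and MSI tables


def write_cnv_table(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for p in cohort:
        for s in p.samples:
            for c in s.cnv_calls:
                rows.append({
                    "sample_id": s.sample_id,
                    "gene": c.gene,
                    "fold_change": repr(c.fold_change),
                    "material": c.material,
                    "gistic_category": "" if c.gistic_category is None else c.gistic_category,
                })
    pd.DataFrame(rows, columns=["sample_id", "gene", "fold_change", "material",
                                "gistic_category"]).to_csv(path, sep="\t", index=False)


def read_cnv_table(path: str | Path) -> dict[str, list[CopyNumberCall]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[CopyNumberCall]] = {}
    for row in df.to_dict("records"):
        gc = row.get("gistic_category")
        out.setdefault(str(row["sample_id"]), []).append(CopyNumberCall(
            gene=str(row["gene"]),
            fold_change=float(row["fold_change"]),
            material=str(row["material"]),
            gistic_category=None if gc is None or pd.isna(gc) or gc == "" else int(float(gc)),
        ))
    return out


def write_msi_table(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for p in cohort:
        for s in p.samples:
            for prof in s.msi_profiles or []:
                for length in sorted(prof.length_counts):
                    rows.append({
                        "sample_id": s.sample_id, "locus_id": prof.locus_id,
                        "repeat_length": length, "count": prof.length_counts[length],
                        "role": "sample",
                    })
    pd.DataFrame(rows, columns=["sample_id", "locus_id", "repeat_length", "count",
                                "role"]).to_csv(path, sep="\t", index=False)


def read_msi_table(path: str | Path) -> dict[str, list[MsiLocusProfile]]:
    """MSI TSV (sample_id, locus_id, repeat_length, count, role) grouped
    per sample; the panel-of-normals uses role == 'normal'."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    out: dict[str, list[MsiLocusProfile]] = {}
    for (sid, locus), grp in df.groupby(["sample_id", "locus_id"], sort=True):
        out.setdefault(str(sid), []).append(MsiLocusProfile(
            locus_id=str(locus),
            length_counts={int(r): int(c) for r, c in zip(grp["repeat_length"], grp["count"])},
        ))
    return out


# ---------------------------------------------------------------------------
# Cohort directory


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"patients": []}
    for p in cohort:
        meta["patients"].append({
            "patient_id": p.patient_id,
            "inclusion_criteria": sorted(p.inclusion_criteria),
            "prior_detected": [list(t) for t in sorted(p.prior_detected)],
            "panel_membership": sorted(p.panel_membership),
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "material": s.material,
                    "collection_date": s.collection_date.isoformat()
                    if s.collection_date else None,
                }
                for s in p.samples
            ],
        })
    with open(outdir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    calls = [c for p in cohort for s in p.samples for c in s.calls]
    write_variant_table(calls, outdir / "variants.tsv")
    write_cnv_table(cohort, outdir / "cnv.tsv")
    if any(s.msi_profiles for p in cohort for s in p.samples):
        write_msi_table(cohort, outdir / "msi.tsv")


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    with open(indir / "cohort.yaml") as fh:
        meta = yaml.safe_load(fh)
    calls = read_variant_table(indir / "variants.tsv")
    by_sample: dict[str, list[VariantCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)
    cnv = read_cnv_table(indir / "cnv.tsv") if (indir / "cnv.tsv").exists() else {}
    msi = read_msi_table(indir / "msi.tsv") if (indir / "msi.tsv").exists() else {}
    patients = []
    for pm in meta["patients"]:
        samples = []
        for sm in pm["samples"]:
            sid = sm["sample_id"]
            samples.append(SampleRecord(
                sample_id=sid,
                patient_id=pm["patient_id"],
                material=sm["material"],
                collection_date=_dt.date.fromisoformat(sm["collection_date"])
                if sm.get("collection_date") else None,
                calls=by_sample.get(sid, []),
                cnv_calls=cnv.get(sid, []),
                msi_profiles=msi.get(sid) or None,
            ))
        patients.append(PatientRecord(
            patient_id=pm["patient_id"],
            inclusion_criteria=set(pm["inclusion_criteria"]),
            samples=samples,
            prior_detected={tuple(t) for t in pm.get("prior_detected", [])},
            panel_membership=set(pm.get("panel_membership", [])),
        ))
    return Cohort(patients)
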