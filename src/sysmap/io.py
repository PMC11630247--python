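"""Readers and writers for the package's file formats.

Phenotypes travel as long CSV (sample_id, genotype_id, replicate, time_min,
trait, value, unit); genotypes as either a samples x SNPs dosage CSV or a
biallelic VCF (GT field -> dosage 0/1/2, "." -> missing); scan and
theta_cri results as TSV; models, fits, truth and run manifests as JSON.
Every writer/reader pair is a lossless round trip on simulator output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GenotypeMatrix, ScanResult
from .data import PHENOTYPE_COLUMNS, TrajectorySet
from .errors import SchemaError, ValidationError
from .thresholds import ThetaCriFit

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(traj_set: TrajectorySet, path) -> None:
    traj_set.to_frame().to_csv(path, index=False)


def read_phenotypes(path, traits=None, grid_minutes: float = 3.0) -> TrajectorySet:
    """Load a long-format phenotype CSV into a validated TrajectorySet.

    Unparseable numeric cells become missing observations (with a counted
    warning); a missing required column or duplicated
    (sample, trait, time) rows raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "genotype_id": str, "trait": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    values = pd.to_numeric(df["value"], errors="coerce")
    n_bad = int((values.isna() & df["value"].notna()).sum())
    if n_bad:
        log.warning("%s: %d unparseable value cell(s) treated as missing", path, n_bad)
    df = df.assign(value=values, time_min=pd.to_numeric(df["time_min"], errors="raise"))
    dup = df.duplicated(subset=["sample_id", "trait", "time_min"])
    if dup.any():
        rows = df.loc[dup, ["sample_id", "trait", "time_min"]].head(3)
        raise SchemaError(
            f"{path}: {int(dup.sum())} duplicate (sample, trait, time) row(s), "
            f"e.g.\n{rows.to_string(index=False)}"
        )
    ts = TrajectorySet.from_frame(df, traits=traits, grid_minutes=grid_minutes)
    n_missing = sum(tr.values.size - tr.n_observed for tr in ts.trajectories)
    n_total = sum(tr.values.size for tr in ts.trajectories)
    span = (
        min(tr.times[0] for tr in ts.trajectories),
        max(tr.times[-1] for tr in ts.trajectories),
    )
    log.info(
        "%s: %d samples, traits %s, span %.0f-%.0f min, %.2f%% missing",
        path, len(ts.sample_ids), ts.traits, span[0], span[1],
        100.0 * n_missing / max(n_total, 1),
    )
    return ts


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_csv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.codes, columns=G.snp_ids)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, index=False, float_format="%.0f")


def read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'sample_id' column")
    snp_ids = [c for c in df.columns if c != "sample_id"]
    codes = df[snp_ids].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return GenotypeMatrix(
        sample_ids=df["sample_id"].tolist(), snp_ids=snp_ids, codes=codes
    )


_GT_FROM_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal biallelic GT-only VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if G.positions is not None:
            for chrom in dict.fromkeys(str(c) for c in G.positions["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids) + "\n"
        )
        for s, snp in enumerate(G.snp_ids):
            if G.positions is not None:
                chrom = str(G.positions.loc[snp, "chrom"])
                pos = int(G.positions.loc[snp, "pos"])
            else:
                chrom, pos = "1", s + 1
            gts = [
                "./." if not np.isfinite(d) else _GT_FROM_DOSAGE[int(d)]
                for d in G.codes[:, s]
            ]
            fh.write(
                f"{chrom}\t{pos}\t{snp}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Biallelic VCF -> dosage matrix; multiallelic rows skipped, counted."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, rows, chroms, poss = [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        dos = np.empty(len(sample_ids))
        for i, g in enumerate(v.genotypes):
            a = [x for x in g[:-1] if x is not None]
            if len(a) < 2 or min(a) < 0:
                dos[i] = np.nan
            else:
                dos[i] = float(a[0] + a[1])
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        rows.append(dos)
    if n_multi:
        log.warning("%s: skipped %d multiallelic site(s)", path, n_multi)
    if not rows:
        raise SchemaError(f"{path}: no usable biallelic sites")
    positions = pd.DataFrame({"chrom": chroms, "pos": poss}, index=snp_ids)
    return GenotypeMatrix(
        sample_ids=sample_ids, snp_ids=snp_ids,
        codes=np.asarray(rows).T, positions=positions,
    )


def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF, otherwise dosage CSV."""
    p = Path(path)
    if p.suffix.lower() in (".vcf", ".bcf") or str(p).endswith(".vcf.gz"):
        return read_vcf(p)
    return read_genotypes_csv(p)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_scan_tsv(result: ScanResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_theta_cri_tsv(fits: dict[str, ThetaCriFit], path) -> None:
    rows = [{"genotype_id": gid, **f.to_dict()} for gid, f in fits.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int | None, inputs: dict | None = None) -> None:
    """Machine-readable record of a run: config, seed, version, input hashes."""
    from . import __version__

    doc = {
        "sysmap_version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
            if Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_config(path) -> dict:
    """YAML run-configuration file -> dict (empty file -> empty dict)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return doc
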