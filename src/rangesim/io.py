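"""Readers and writers for the on-disk run formats.

Time series, population snapshots and pedigrees are TSV; statistics and
ancestry clouds are tidy CSV; sampled genotypes are VCF (diploid GT,
positions rounded to integer bp on chromosome "1"); the run manifest is
JSON (config hash, seeds, package version).  Re-running the statistics on
the written files reproduces the in-memory values (tested round-trip);
VCF-derived statistics agree up to the rare sites whose continuous
positions collide after rounding to integer base pairs (merged records).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .simcore import SampleGroup, SimResult

__all__ = [
    "write_vcf",
    "read_vcf_haplotypes",
    "write_run",
    "write_experiment",
    "config_hash",
]


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# VCF


def write_vcf(group: SampleGroup, genome_length: int, path) -> int:
    """Write a sampled group's genotypes as a VCF.

    Mutation positions are rounded to integer base pairs (1-based) on
    chromosome "1"; sites whose rounded positions collide are merged into
    one record (logged in the header as a comment is not possible, so the
    return value is the number of records written).  Alleles are synthetic
    A/T since the infinite-sites model stores no nucleotide state.
    """
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=1,length={int(genome_length)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    names = [f"ind{int(i)}" for i in group.ids]
    for nm in names:
        header.add_sample(nm)
    haps = []
    for ha, hb in group.haplotypes:
        haps.append(ha.muts if hasattr(ha, "muts") else np.asarray(ha))
        haps.append(hb.muts if hasattr(hb, "muts") else np.asarray(hb))
    allpos = np.unique(np.concatenate(haps)) if haps else np.empty(0)
    bp = np.minimum(np.floor(allpos).astype(np.int64) + 1, int(genome_length))
    # presence matrix: haplotype x site
    carry = np.zeros((len(haps), len(allpos)), dtype=bool)
    for k, h in enumerate(haps):
        carry[k, np.searchsorted(allpos, h)] = True
    # merge records that round to the same bp
    uniq_bp, inv = np.unique(bp, return_inverse=True)
    merged = np.zeros((len(haps), len(uniq_bp)), dtype=bool)
    np.logical_or.at(merged.T, inv, carry.T)
    n_written = 0
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s, pos1 in enumerate(uniq_bp):
            rec = vf.new_record(contig="1", start=int(pos1) - 1, alleles=("A", "T"))
            for k, nm in enumerate(names):
                rec.samples[nm]["GT"] = (int(merged[2 * k, s]), int(merged[2 * k + 1, s]))
                rec.samples[nm].phased = True
            vf.write(rec)
            n_written += 1
    return n_written


def read_vcf_haplotypes(path):
    """Read a VCF written by :func:`write_vcf` back into haplotype arrays.

    Returns (sample_names, list of (hapA_positions, hapB_positions)) with
    1-based integer positions as floats, suitable for the diversity
    statistics.
    """
    with pysam.VariantFile(str(path)) as vf:
        names = list(vf.header.samples)
        pos, gts = [], []
        for rec in vf:
            pos.append(rec.pos)
            gts.append([rec.samples[nm]["GT"] for nm in names])
    pos = np.asarray(pos, dtype=float)
    out = []
    for k in range(len(names)):
        a = np.array([g[k][0] == 1 for g in gts], dtype=bool)
        b = np.array([g[k][1] == 1 for g in gts], dtype=bool)
        out.append((pos[a], pos[b]))
    return names, out


# ---------------------------------------------------------------------------
# run and experiment directories


def write_run(result: SimResult, outdir, config_dict: dict | None = None) -> dict:
    """Persist one replicate run; returns the manifest dict.

    Writes timeseries.tsv, population.tsv (final snapshot), pedigree.tsv,
    one VCF per sampled group, ancestry.csv and manifest.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.timeseries.to_csv(out / "timeseries.tsv", sep="\t", index=False)
    if result.final_population is not None:
        result.final_population.to_csv(out / "population.tsv", sep="\t", index=False)
    result.pedigree.to_frame().to_csv(out / "pedigree.tsv", sep="\t", index=False)
    G = int(result.params.genome_length)
    vcfs = {}
    for label, grp in {**result.samples, **result.region_samples}.items():
        if grp.n:
            fn = f"sample_{label}.vcf"
            write_vcf(grp, G, out / fn)
            vcfs[label] = fn
    from .pipeline import ancestry_cloud  # local import avoids a cycle

    anc = ancestry_cloud(result)
    if len(anc):
        anc.to_csv(out / "ancestry.csv", index=False)
    manifest = {
        "kind": "run",
        "version": __version__,
        "seed": int(result.seed),
        "scenario": result.schedule.pattern,
        "extinct": bool(result.extinct),
        "final_n": int(result.final_n),
        "tables": ["timeseries.tsv", "population.tsv", "pedigree.tsv"],
        "vcfs": vcfs,
        "config_hash": config_hash(config_dict) if config_dict else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_experiment(experiment, outdir, config_dict: dict | None = None) -> dict:
    """Persist an ExperimentResult's aggregate tables; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "timeseries.tsv": (experiment.timeseries, "\t"),
        "seeds.tsv": (experiment.seeds, "\t"),
        "diversity.csv": (experiment.diversity, ","),
        "fst.csv": (experiment.fst, ","),
        "declines.csv": (experiment.declines, ","),
        "relatedness.csv": (experiment.relatedness, ","),
        "ancestry.csv": (experiment.ancestry, ","),
    }
    written = []
    for name, (df, sep) in tables.items():
        if df is not None and len(df):
            df.to_csv(out / name, sep=sep, index=False)
            written.append(name)
    manifest = {
        "kind": "experiment",
        "version": __version__,
        "master_seed": int(experiment.master_seed),
        "scenarios": list(experiment.scenarios),
        "n_replicates": int(experiment.n_replicates),
        "extinctions": experiment.extinctions,
        "tables": written,
        "config_hash": config_hash(config_dict) if config_dict else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
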