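"""File formats: dosage VCF (DS/GP), a TSV panel dialect, phenotype tables,
allele-frequency spectra, trait estimate sets, and GRM caching."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .heritability import FreqSpectrum
from .meta import TraitEstimateSet
from .reml import GRM
from .simdata import GenotypePanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_panel_tsv",
    "read_panel_tsv",
    "read_phenotypes",
    "read_spectrum_tsv",
    "read_estimates_tsv",
    "save_grm",
    "load_grm",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=alphafreq
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage (expected minor allele count)">
##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype probabilities">
##contig=<ID=1>
"""


def write_vcf(panel: GenotypePanel, path: Union[str, Path]) -> None:
    """Write a panel as a dosage VCF (DS format field, GP when present)."""
    path = Path(path)
    has_gp = panel.probs is not None
    fmt = "GT:DS:GP" if has_gp else "GT:DS"
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j in range(panel.n_snps):
            fields = [
                "1",
                str(int(panel.positions[j])),
                panel.snp_ids[j],
                "A",
                "C",
                ".",
                "PASS",
                f"AF={panel.maf[j]:.6g}",
                fmt,
            ]
            ds = panel.dosages[:, j]
            gt = np.rint(ds).astype(int)
            gt_str = np.array(["0/0", "0/1", "1/1"])[np.clip(gt, 0, 2)]
            if has_gp:
                gp = panel.probs[:, j, :]
                cells = [
                    f"{g}:{d:.4g}:{p[0]:.4g},{p[1]:.4g},{p[2]:.4g}"
                    for g, d, p in zip(gt_str, ds, gp)
                ]
            else:
                cells = [f"{g}:{d:.4g}" for g, d in zip(gt_str, ds)]
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path: Union[str, Path]) -> GenotypePanel:
    """Read a dosage VCF (DS field; GP when present) into a panel."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosages, positions, snp_ids, probs = [], [], [], []
    has_gp = True
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"{path}: missing DS field at {var.POS}")
        dosages.append(np.asarray(ds, dtype=float).ravel())
        positions.append(var.POS)
        snp_ids.append(var.ID or f"snp_{var.POS}")
        gp = var.format("GP")
        if gp is None:
            has_gp = False
        elif has_gp:
            probs.append(np.asarray(gp, dtype=float))
    X = np.column_stack(dosages)
    maf = X.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)
    return GenotypePanel(
        dosages=X,
        maf=maf,
        positions=np.asarray(positions),
        probs=np.stack(probs, axis=1) if has_gp and probs else None,
        sample_ids=sample_ids,
        snp_ids=snp_ids,
    )


def write_panel_tsv(panel: GenotypePanel, path: Union[str, Path]) -> None:
    """One SNP per row: snp_id, pos, maf, then per-sample dosages."""
    df = pd.DataFrame(
        panel.dosages.T, columns=list(panel.sample_ids)
    )
    df.insert(0, "maf", panel.maf)
    df.insert(0, "pos", panel.positions)
    df.insert(0, "snp_id", list(panel.snp_ids))
    df.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: Union[str, Path]) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    meta = ["snp_id", "pos", "maf"]
    samples = [c for c in df.columns if c not in meta]
    return GenotypePanel(
        dosages=df[samples].to_numpy().T,
        maf=df["maf"].to_numpy(),
        positions=df["pos"].to_numpy(),
        sample_ids=samples,
        snp_ids=df["snp_id"].astype(str).tolist(),
    )


def read_phenotypes(path: Union[str, Path]) -> pd.DataFrame:
    """Phenotype/covariate TSV with a sample_id column and a value column."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "value" not in df.columns:
        raise ValueError("phenotype TSV needs sample_id and value columns")
    return df


def read_spectrum_tsv(path: Union[str, Path]) -> FreqSpectrum:
    """Binned allele-frequency spectrum: maf_bin_low, maf_bin_high, count."""
    df = pd.read_csv(path, sep="\t")
    return FreqSpectrum.from_bins(
        df["maf_bin_low"].to_numpy(),
        df["maf_bin_high"].to_numpy(),
        df["count"].to_numpy(),
    )


def read_estimates_tsv(path: Union[str, Path]) -> TraitEstimateSet:
    """Per-trait estimates: trait_id, alpha_hat, se."""
    df = pd.read_csv(path, sep="\t")
    return TraitEstimateSet(
        trait_ids=df["trait_id"].astype(str).tolist(),
        alpha_hat=df["alpha_hat"].to_numpy(),
        se=df["se"].to_numpy(),
    )


def save_grm(grm: GRM, path: Union[str, Path]) -> None:
    """Cache a GRM as .npy with a JSON sidecar recording its construction."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), grm.matrix)
    sidecar = {
        "normalizer": grm.normalizer,
        "alpha_used": grm.alpha_used,
        "tau_star_used": grm.tau_star_used,
        "n_snps_used": grm.n_snps_used,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_grm(path: Union[str, Path]) -> GRM:
    path = Path(path)
    matrix = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return GRM(matrix=matrix, **meta)
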