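"""File formats: genotype matrix + map, phenotypes, VCF export, result TSVs.

Genotypes travel as a tab-delimited matrix (rows = individuals, columns =
SNPs, values 0/1/2 counting mutant alleles) next to a 3-column map file
(snp_id, position_cm, position_bp).  Result tables are TSVs with a leading
provenance comment line recording the package version, the master seed and
a hash of the generating configuration, so any published file can be traced
back to the run that made it.  Missing genotypes are not supported and are
rejected on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .popsim import Population

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_vcf",
    "write_qtl_table",
    "config_hash",
    "write_table",
    "read_table",
]

_VERSION = "0.1.0"


def write_genotypes(prefix, pop: Population, sites=None) -> None:
    """Write <prefix>.geno.tsv (N x S dosages) and <prefix>.map.tsv."""
    prefix = Path(prefix)
    idx = (
        np.arange(pop.n_sites)
        if sites is None
        else np.asarray(sites, dtype=np.int64)
    )
    x = pop.genotypes(idx)
    np.savetxt(prefix.with_suffix(".geno.tsv"), x, fmt="%d", delimiter="\t")
    pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in idx],
            "position_cm": pop.positions_cm[idx],
            "position_bp": pop.positions_bp[idx].astype(np.int64),
        }
    ).to_csv(prefix.with_suffix(".map.tsv"), sep="\t", index=False)


def read_genotypes(prefix) -> Tuple[np.ndarray, pd.DataFrame]:
    """Read the genotype matrix and map written by :func:`write_genotypes`.

    Returns (X, map_frame) with X int8 0/1/2.  Rejects non-{0,1,2} entries,
    dimension mismatches and unsorted maps.
    """
    prefix = Path(prefix)
    x = np.loadtxt(prefix.with_suffix(".geno.tsv"), delimiter="\t", ndmin=2)
    if not np.isin(x, (0, 1, 2)).all():
        raise ValueError("genotype entries must be 0/1/2 (no missing values)")
    snpmap = pd.read_csv(prefix.with_suffix(".map.tsv"), sep="\t")
    if len(snpmap) != x.shape[1]:
        raise ValueError(
            f"map lists {len(snpmap)} SNPs but matrix has {x.shape[1]} columns"
        )
    pos = snpmap["position_cm"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("map positions must be sorted")
    return x.astype(np.int8), snpmap


def write_phenotypes(path, y: np.ndarray, ids=None) -> None:
    ids = ids if ids is not None else [f"ind{i}" for i in range(len(y))]
    pd.DataFrame({"individual_id": ids, "y": y}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    y = df["y"].to_numpy(dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("phenotypes must be finite (no missing values)")
    return y


def write_vcf(path, pop: Population, sites=None) -> None:
    """Export phased haplotypes as a minimal VCF 4.2 with GT fields.

    The mutant (derived) allele is written as ALT allele ``T`` on REF ``A``
    placeholders; physical positions are 1-based.
    """
    idx = (
        np.arange(pop.n_sites)
        if sites is None
        else np.asarray(sites, dtype=np.int64)
    )
    hap = pop.haplotypes
    n = pop.n_individuals
    with open(path, "w") as f:
        f.write("##fileformat=VCFv4.2\n")
        f.write(f"##source=dombayes-{_VERSION}\n")
        f.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        f.write(f"##contig=<ID=1,length={int(pop.positions_bp.max()) + 1}>\n")
        cols = "\t".join(f"ind{i}" for i in range(n))
        f.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + cols + "\n"
        )
        for j in idx:
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(n)
            )
            f.write(
                f"1\t{int(pop.positions_bp[j]) + 1}\tsnp{j}\tA\tT\t.\tPASS"
                f"\t.\tGT\t{gts}\n"
            )


def write_qtl_table(path, qtl, trait=None) -> None:
    H = 2.0 * qtl.p * (1.0 - qtl.p)
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in qtl.site_ids],
            "position_cm": qtl.positions_cm,
            "p": qtl.p,
            "a": qtl.a,
            "d": qtl.d,
            "h": qtl.h,
            "variance": qtl.variance_contributions(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def config_hash(config) -> str:
    """Stable short hash of a (nested, JSON-serialisable) configuration."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(config, sort_keys=True, default=_default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(path, df: pd.DataFrame, config=None, seed=None) -> None:
    """TSV with a provenance comment line (version, seed, config hash)."""
    chash = config_hash(config) if config is not None else "none"
    with open(path, "w") as f:
        f.write(
            f"# dombayes={_VERSION} seed={seed} config_hash={chash}\n"
        )
        df.to_csv(f, sep="\t", index=False)


def read_table(path) -> Tuple[pd.DataFrame, dict]:
    """Read a provenance TSV; returns (frame, provenance dict)."""
    with open(path) as f:
        first = f.readline()
    prov = {}
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                prov[k] = v
        df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    else:
        df = pd.read_csv(path, sep="\t")
    return df, prov
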