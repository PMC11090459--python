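"""Tabular input/output for plaintext and cyphertext datasets.

Plaintext genotypes: CSV with a header row of marker ids and the individual
id in the first column, or PLINK-style ``.raw`` text (whitespace-delimited,
``FID IID PAT MAT SEX PHENOTYPE`` then one dosage column per marker).
Cyphertext: CSV with the marker-id header and *no* row identifiers, plus a
JSON sidecar carrying the contributor tag and block boundaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crypt import CipherDataset, PlainDataset
from .exceptions import InvalidArgumentError

__all__ = [
    "read_genotype_csv",
    "write_genotype_csv",
    "read_plink_raw",
    "read_phenotype_csv",
    "read_covariate_csv",
    "write_cipher",
    "read_cipher",
]

_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotype_csv(path) -> tuple[list[str], list[str], np.ndarray]:
    """(individual_ids, marker_ids, M) from an individuals x markers CSV."""
    df = pd.read_csv(path, index_col=0)
    return [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=np.float64)


def write_genotype_csv(path, individual_ids, marker_ids, M) -> None:
    pd.DataFrame(M, index=list(individual_ids), columns=list(marker_ids)).to_csv(path)


def read_plink_raw(path) -> tuple[list[str], list[str], np.ndarray]:
    """(individual_ids, marker_ids, M) from a PLINK ``--recode A`` .raw file."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _RAW_META_COLS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f".raw file lacks columns {missing}")
    ids = [str(i) for i in df["IID"]]
    geno = df.drop(columns=_RAW_META_COLS)
    return ids, [str(c) for c in geno.columns], geno.to_numpy(dtype=np.float64)


def read_phenotype_csv(path) -> tuple[list[str], np.ndarray]:
    """(individual_ids, y) from a two-column id,value CSV."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise InvalidArgumentError("phenotype CSV must have exactly one value column")
    return [str(i) for i in df.index], df.iloc[:, 0].to_numpy(dtype=np.float64)


def read_covariate_csv(path) -> tuple[list[str], np.ndarray]:
    """(individual_ids, X) from an id + covariate-columns CSV.

    X must already include its intercept column if one is wanted.
    """
    df = pd.read_csv(path, index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=np.float64)


def write_cipher(prefix, cipher: CipherDataset) -> None:
    """Write ``<prefix>.geno.csv``, ``.pheno.csv``, ``.covar.csv``, ``.meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cipher.M_star, columns=cipher.marker_ids).to_csv(
        f"{prefix}.geno.csv", index=False
    )
    pd.DataFrame({"y_star": cipher.y_star}).to_csv(f"{prefix}.pheno.csv", index=False)
    pd.DataFrame(
        cipher.X_star, columns=[f"x{j}" for j in range(cipher.X_star.shape[1])]
    ).to_csv(f"{prefix}.covar.csv", index=False)
    meta = {
        "contributor_tag": cipher.contributor_tag,
        "block_sizes": list(cipher.block_sizes) if cipher.block_sizes else None,
    }
    Path(f"{prefix}.meta.json").write_text(json.dumps(meta))


def read_cipher(prefix) -> CipherDataset:
    geno = pd.read_csv(f"{prefix}.geno.csv")
    pheno = pd.read_csv(f"{prefix}.pheno.csv")
    covar = pd.read_csv(f"{prefix}.covar.csv")
    meta_path = Path(f"{prefix}.meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    blocks = meta.get("block_sizes")
    return CipherDataset(
        y_star=pheno.iloc[:, 0].to_numpy(dtype=np.float64),
        X_star=covar.to_numpy(dtype=np.float64),
        M_star=geno.to_numpy(dtype=np.float64),
        marker_ids=[str(c) for c in geno.columns],
        contributor_tag=meta.get("contributor_tag"),
        block_sizes=tuple(blocks) if blocks else None,
    )
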