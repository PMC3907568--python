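"""Readers and writers for genotype tables, relationship matrices,
predictions and analysis reports.

Genotype dialects
-----------------
* PLINK ``.raw``-style: whitespace-delimited, header starting with
  ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column per SNP; one
  row per individual with 0/1/2 allele counts.  The ``IID`` column is the
  individual ID.
* plain TSV: header ``id <snp ids...>``, one row per individual.

Missing genotypes are rejected with an error pointing at the offending
line — impute before import.  Relationship matrices are written both as
dense TSV (with IDs) and in the GCTA text convention (lower triangle,
columns ``i j m value`` with 1-based indices, plus a ``.id`` file).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coding import GenotypeMatrix
from .errors import InputError
from .gblup_ce import PredictionSet
from .grm import RelationshipPair

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes_raw",
    "read_phenotypes",
    "write_grm",
    "read_grm",
    "write_predictions",
    "write_report",
    "config_hash",
]

_RAW_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
_VALID_TOKENS = {"0", "1", "2"}


def read_genotypes(path, maf_threshold: float = 0.0) -> GenotypeMatrix:
    """Read a genotype table (``.raw`` or plain TSV dialect, auto-detected
    from the header), validate tokens and apply the MAF filter."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise InputError(f"{path}: empty file")
        if header[0] == "FID":
            if tuple(header[:6]) != _RAW_META:
                raise InputError(f"{path}: malformed .raw header")
            snp_ids = header[6:]
            skip, id_col = 6, 1
        else:
            snp_ids = header[1:]
            skip, id_col = 1, 0
        if not snp_ids:
            raise InputError(f"{path}: no SNP columns")
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != skip + len(snp_ids):
                raise InputError(
                    f"{path}:{lineno}: expected {skip + len(snp_ids)} fields, got {len(parts)}"
                )
            for tok in parts[skip:]:
                if tok not in _VALID_TOKENS:
                    raise InputError(
                        f"{path}:{lineno}: invalid genotype token {tok!r} "
                        "(missing values must be imputed beforehand)"
                    )
            ids.append(parts[id_col])
            rows.append(np.array(parts[skip:], dtype=np.int8))
    if not rows:
        raise InputError(f"{path}: no genotype rows")
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate individual IDs")
    gm = GenotypeMatrix.from_counts(np.vstack(rows), snp_ids=snp_ids, individual_ids=ids)
    before = gm.m
    gm = gm.filter_maf(maf_threshold)
    logger.info("read %d individuals x %d SNPs (%d dropped by MAF filter)",
                gm.q, gm.m, before - gm.m)
    return gm


def write_genotypes_raw(gm: GenotypeMatrix, path) -> None:
    """Write the PLINK ``.raw``-style dialect."""
    with open(path, "w") as fh:
        fh.write(" ".join(_RAW_META) + " " + " ".join(map(str, gm.snp_ids)) + "\n")
        for i, iid in enumerate(gm.individual_ids):
            fh.write(
                f"{iid} {iid} 0 0 0 -9 " + " ".join(map(str, gm.counts[i].tolist())) + "\n"
            )


def read_phenotypes(path, id_col: str = "id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if id_col not in df.columns:
        raise InputError(f"{path}: no {id_col!r} column")
    df[id_col] = df[id_col].astype(str)
    return df


def write_grm(pair: RelationshipPair, prefix, individual_ids, extra_meta: dict | None = None) -> None:
    """Write ``<prefix>.G.tsv`` / ``<prefix>.D.tsv`` (dense, with IDs),
    ``<prefix>.ids`` and GCTA-style ``<prefix>.{A,D}.grm.txt`` triangles."""
    prefix = str(prefix)
    ids = list(map(str, individual_ids))
    m_meta = (extra_meta or {}).get("n_snps", 0)
    for tag, M in (("G", pair.G), ("D", pair.D)):
        pd.DataFrame(M, index=ids, columns=ids).to_csv(f"{prefix}.{tag}.tsv", sep="\t")
    with open(f"{prefix}.ids", "w") as fh:
        fh.write("\n".join(ids) + "\n")
    for tag, M in (("A", pair.G), ("D", pair.D)):
        with open(f"{prefix}.{tag}.grm.txt", "w") as fh:
            q = M.shape[0]
            for i in range(q):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{m_meta}\t{float(M[i, j])!r}\n")


def read_grm(prefix, matrix: str = "A") -> tuple[np.ndarray, list]:
    """Read a GCTA-style triangle written by :func:`write_grm`."""
    prefix = str(prefix)
    with open(f"{prefix}.ids") as fh:
        ids = [ln.strip() for ln in fh if ln.strip()]
    q = len(ids)
    M = np.zeros((q, q))
    with open(f"{prefix}.{matrix}.grm.txt") as fh:
        for ln in fh:
            i, j, _, v = ln.split("\t")
            M[int(i) - 1, int(j) - 1] = M[int(j) - 1, int(i) - 1] = float(v)
    return M, ids


def write_predictions(pred: PredictionSet, path, config_digest: str | None = None) -> None:
    df = pred.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# gdblup {__version__}")
        if config_digest:
            fh.write(f" config={config_digest}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


_REPORT_REQUIRED = ("variance_components", "heritabilities")


def write_report(report: dict, path, config: dict | None = None) -> None:
    """JSON report with variance components, heritabilities, SEs and a
    trace summary; stamps the tool version and a config hash."""
    missing = [k for k in _REPORT_REQUIRED if k not in report]
    if missing:
        raise InputError(f"report is missing required key(s): {missing}")
    payload = dict(report)
    payload["tool_version"] = __version__
    payload["config_hash"] = config_hash(config or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
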