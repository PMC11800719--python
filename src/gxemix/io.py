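"""Readers and writers for the standard formats touched by the tool.

Genotypes use PLINK 1 binary (.bed/.bim/.fam, SNP-major); kinship matrices
are exchanged either as dense tab-delimited text with a sample-id header or
as GCTA-style binary (``.grm.bin`` float32 lower triangle plus a
``.grm.id`` text file); covariates, phenotypes and fitted results are
tab-delimited text / JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GenotypePanel
from .null_model import NullFit
from .penalized_path import PathPoint

__all__ = [
    "read_plink",
    "write_plink",
    "read_kinship_text",
    "write_kinship_text",
    "read_grm_gcta",
    "write_grm_gcta",
    "read_table",
    "write_null_fit",
    "read_null_fit",
    "write_path_results",
    "odds_ratio_table",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> A1-allele count (1 = missing)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK 1 fileset ``prefix.{bed,bim,fam}`` into a panel.

    Decoding follows the SNP-major .bed standard: per byte, four samples in
    little-endian 2-bit pairs with 00 -> two copies of A1, 10 -> one,
    11 -> zero, 01 -> missing.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype=str,
    )
    n, p = len(fam), len(bim)
    raw = Path(str(prefix) + ".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC[:2]:
        raise ValueError("not a PLINK .bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise ValueError("only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise ValueError(
            f".bed truncated or oversized: expected {expected} bytes, "
            f"got {len(raw)} (first bad offset {min(expected, len(raw))})"
        )
    if n == 0 or p == 0:
        G = np.zeros((n, p))
    else:
        buf = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
        shifts = np.arange(4, dtype=np.uint8) * 2
        codes = (buf[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(p, -1)[:, :n]
        G = _BED_DECODE[codes].T  # n x p
    return GenotypePanel(
        G,
        sample_ids=list(fam["iid"]),
        snp_ids=list(bim["snp"]),
    )


def write_plink(
    panel: GenotypePanel,
    prefix: str | Path,
    chrom: str = "1",
    positions: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
) -> None:
    """Write a panel as a PLINK 1 fileset (A1 = counted allele 'A',
    A2 = 'B')."""
    prefix = Path(prefix)
    n, p = panel.n_samples, panel.n_snps
    sex_col = (
        np.zeros(n, dtype=int) if sex is None
        else np.asarray(sex, dtype=int) + 1  # PLINK: 1=male, 2=female
    )
    phe = (
        np.full(n, -9, dtype=object) if phenotype is None
        else np.asarray(phenotype, dtype=int) + 1  # PLINK case/control: 1/2
    )
    with open(Path(str(prefix) + ".fam"), "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fh.write(f"{sid} {sid} 0 0 {sex_col[i]} {phe[i]}\n")
    pos = np.arange(1, p + 1) if positions is None else positions
    with open(Path(str(prefix) + ".bim"), "w") as fh:
        for j, sid in enumerate(panel.snp_ids):
            fh.write(f"{chrom} {sid} 0 {pos[j]} A B\n")

    G = panel.G.T  # SNP-major
    codes = np.full(G.shape, 1, dtype=np.uint8)  # missing
    codes[G == 2.0] = 0b00
    codes[G == 1.0] = 0b10
    codes[G == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0b01)
    codes = codes.reshape(p, -1, 4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = np.bitwise_or.reduce(codes << shifts[None, None, :], axis=2)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def write_kinship_text(K: np.ndarray, sample_ids, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(K, dtype=float), columns=list(sample_ids))
    df.to_csv(path, sep="\t", index=False)


def read_kinship_text(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_grm_gcta(K: np.ndarray, sample_ids, prefix: str | Path) -> None:
    """GCTA binary GRM: float32 lower triangle (row-major, including the
    diagonal) in ``prefix.grm.bin`` and ids in ``prefix.grm.id``."""
    prefix = Path(prefix)
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    tri = K[np.tril_indices(n)].astype("<f4")
    Path(str(prefix) + ".grm.bin").write_bytes(tri.tobytes())
    with open(str(prefix) + ".grm.id", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix: str | Path) -> tuple[np.ndarray, list[str]]:
    prefix = Path(prefix)
    ids = [
        line.split()[1]
        for line in Path(str(prefix) + ".grm.id").read_text().splitlines()
        if line.strip()
    ]
    n = len(ids)
    tri = np.frombuffer(Path(str(prefix) + ".grm.bin").read_bytes(), dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError("GRM binary size inconsistent with id file")
    K = np.zeros((n, n))
    K[np.tril_indices(n)] = tri
    K = K + np.tril(K, -1).T
    return K, ids


def read_table(path: str | Path) -> pd.DataFrame:
    """Delimited text table with named columns (tab or comma)."""
    return pd.read_csv(path, sep=None, engine="python")


def write_null_fit(fit: NullFit, out_dir: str | Path, prefix: str = "null") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scalars = {
        "theta": list(map(float, fit.theta)),
        "alpha": fit.alpha,
        "tau_g": fit.tau_g,
        "tau_d": fit.tau_d,
        "phi": fit.phi,
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
    }
    (out_dir / f"{prefix}.json").write_text(json.dumps(scalars, indent=1))
    pd.DataFrame({"b": fit.b}).to_csv(out_dir / f"{prefix}_ranef.tsv",
                                      sep="\t", index=False)


def read_null_fit(out_dir: str | Path, prefix: str = "null") -> NullFit:
    out_dir = Path(out_dir)
    scalars = json.loads((out_dir / f"{prefix}.json").read_text())
    b = pd.read_csv(out_dir / f"{prefix}_ranef.tsv", sep="\t")["b"].to_numpy()
    return NullFit(
        theta=np.array(scalars["theta"], dtype=float),
        alpha=float(scalars["alpha"]),
        tau_g=float(scalars["tau_g"]),
        tau_d=float(scalars["tau_d"]),
        phi=float(scalars["phi"]),
        b=b,
        converged=bool(scalars["converged"]),
        n_iter=int(scalars["n_iter"]),
    )


def odds_ratio_table(
    beta: np.ndarray, gamma: np.ndarray, snp_ids=None
) -> pd.DataFrame:
    """Odds ratios exp(beta), exp(gamma) and exp(beta+gamma) for the
    selected SNPs (rows with any nonzero coefficient)."""
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    sel = np.flatnonzero((beta != 0) | (gamma != 0))
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(beta.size)]
    rows = []
    for j in sel:
        rows.append(
            {
                "snp": ids[j],
                "beta": beta[j],
                "gamma": gamma[j],
                "or_beta": np.exp(beta[j]),
                "or_gamma": np.exp(gamma[j]) if gamma[j] != 0 else np.nan,
                "or_beta_plus_gamma": (
                    np.exp(beta[j] + gamma[j]) if gamma[j] != 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp", "beta", "gamma", "or_beta", "or_gamma",
                 "or_beta_plus_gamma"],
    )


def write_path_results(
    points: list[PathPoint],
    out_dir: str | Path,
    snp_ids=None,
    cv_result=None,
) -> None:
    """Long-format coefficient paths, a per-point summary table, the CV
    surface (if given) and the final-model odds-ratio table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coef_rows = []
    summary_rows = []
    for pt in points:
        summary_rows.append(
            {
                "rho": pt.rho, "lambda": pt.lam, "objective": pt.objective,
                "size_main": pt.size_main, "size_gei": pt.size_gei,
                "n_outer": pt.n_outer, "n_inner": pt.n_inner,
                "converged": pt.converged,
            }
        )
        ids = (
            snp_ids if snp_ids is not None
            else [f"snp{j}" for j in range(pt.state.beta.size)]
        )
        for j in np.flatnonzero(pt.state.beta):
            coef_rows.append(
                {"rho": pt.rho, "lambda": pt.lam,
                 "coefficient": f"beta[{ids[j]}]", "value": pt.state.beta[j]}
            )
        for j in np.flatnonzero(pt.state.gamma):
            coef_rows.append(
                {"rho": pt.rho, "lambda": pt.lam,
                 "coefficient": f"gamma[{ids[j]}]", "value": pt.state.gamma[j]}
            )
    pd.DataFrame(
        summary_rows,
        columns=["rho", "lambda", "objective", "size_main", "size_gei",
                 "n_outer", "n_inner", "converged"],
    ).to_csv(out_dir / "path_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        coef_rows, columns=["rho", "lambda", "coefficient", "value"]
    ).to_csv(out_dir / "path_coefficients.tsv", sep="\t", index=False)

    if cv_result is not None:
        surf = []
        for l, lam in enumerate(cv_result.lambda_grid):
            for r, rho in enumerate(cv_result.rho_grid):
                surf.append(
                    {"lambda": lam, "rho": rho,
                     "mean": cv_result.mean_metric[l, r],
                     "se": cv_result.se_metric[l, r]}
                )
        pd.DataFrame(surf).to_csv(out_dir / "cv_surface.tsv", sep="\t",
                                  index=False)
        (out_dir / "cv_choice.json").write_text(
            json.dumps(
                {"lambda": cv_result.best_lambda, "rho": cv_result.best_rho,
                 "metric": cv_result.metric},
                indent=1,
            )
        )
        odds_ratio_table(
            cv_result.final_state.beta, cv_result.final_state.gamma, snp_ids
        ).to_csv(out_dir / "final_model_or.tsv", sep="\t", index=False)
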