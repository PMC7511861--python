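"""Genome-wide region-level EWAS with a strain-by-diet random intercept.

The model fitted independently at every 150-bp bin is

    logRPKM ~ age + BW0 + medianLifeSpan + (1 | StrainDiet)

i.e. fixed effects for age at collection (days), baseline body weight
(grams) and the strain-by-diet group's median life span (days), plus a
random intercept per strain-by-diet group, estimated by REML.

Because the fixed-effect design is identical for every region (only the
response changes), the scan profiles the REML criterion over the variance
ratio lambda = tau^2/sigma^2 on a shared grid, vectorised across all
regions at once, then refines each region's optimum parabolically. For a
one-way random intercept the marginal covariance V = I + lambda*Z*Z' has a
closed-form square-root inverse: subtracting c_g = 1 - 1/sqrt(1 + lambda*n_g)
times the group mean whitens the data, so each criterion evaluation is a
cheap OLS on transformed data. This makes a 10,000-region scan a matter of
seconds rather than the minutes a generic mixed-model fitter needs, while
agreeing with one (see the test suite's cross-checks against
statsmodels MixedLM).

P-values are Wald z by default; a Satterthwaite-style t approximation is
available via ``df_method="satterthwaite"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import LongevityTable, MethylomeMatrix, SampleTable

__all__ = [
    "RegionEWAS",
    "EwasResults",
    "DmrSet",
    "fit_region_mixed_model",
    "run_ewas",
    "bonferroni_threshold",
    "call_dmrs",
]

logger = logging.getLogger(__name__)

TRAITS = ("age", "BW0", "LS")
_TRAIT_COL = {"age": "age", "BW0": "bw0", "LS": "ls"}

# log10(lambda) grid for the profiled REML criterion; lambda = tau^2/sigma^2.
_DEFAULT_GRID = np.concatenate([[0.0], 10.0 ** np.arange(-5.0, 5.0001, 0.05)])


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.10) -> float:
    """Per-test p threshold controlling the family-wise rate at family_alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    return family_alpha / n_tests


@dataclass(frozen=True)
class DmrSet:
    """Regions associated with one trait at a p threshold, with direction."""

    trait: str
    threshold_p: float
    df: pd.DataFrame  # columns: region_id, beta, p, direction

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}")
        if len(self.df) and (self.df["p"] > self.threshold_p).any():
            raise ValueError("DmrSet contains regions above its own threshold")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def region_ids(self) -> list[str]:
        return list(self.df["region_id"])


class _Design:
    """Shared fixed-effect design and grouping for one cohort."""

    def __init__(self, samples: SampleTable, longevity: LongevityTable,
                 lifespan_stat: str = "median"):
        df = samples.df
        median_ls = longevity.stat_for_samples(samples, lifespan_stat)
        self.X = np.column_stack(
            [
                np.ones(len(df)),
                df["age_days"].to_numpy(float),
                df["bw0_g"].to_numpy(float),
                median_ls.to_numpy(),
            ]
        )
        labels = samples.group_labels().to_numpy()
        uniq, self.groups = np.unique(labels, return_inverse=True)
        self.group_names = list(uniq)
        self.counts = np.bincount(self.groups).astype(float)
        if len(uniq) < 2:
            raise ValueError("need >= 2 strain-by-diet groups for a random intercept")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("singular fixed-effect design (collinear covariates)")
        self.n, self.p = self.X.shape
        if len(uniq) <= self.p:
            logger.warning(
                "only %d strain-by-diet groups: the group-level medianLifeSpan "
                "covariate is heavily confounded with the random intercept",
                len(uniq),
            )
        # per-group sums of X, for the whitening transform
        q = len(uniq)
        self.Gx = np.zeros((q, self.p))
        np.add.at(self.Gx, self.groups, self.X)
        self.Gx /= self.counts[:, None]


def _criterion_on_grid(Y: np.ndarray, design: _Design, grid: np.ndarray) -> np.ndarray:
    """-2 profiled REML (up to a constant) for every region at every lambda."""
    n, p = design.n, design.p
    groups, counts = design.groups, design.counts
    q = len(counts)
    Gy = np.zeros((q, Y.shape[1]))
    np.add.at(Gy, groups, Y)
    Gy /= counts[:, None]
    out = np.empty((len(grid), Y.shape[1]))
    ysq_base = Y - Gy[groups]  # reused pieces are cheap; compute directly per lam
    for gi, lam in enumerate(grid):
        c = 1.0 - 1.0 / np.sqrt(1.0 + lam * counts)
        Xt = design.X - c[groups, None] * design.Gx[groups]
        Yt = Y - c[groups, None] * Gy[groups]
        Q, R = np.linalg.qr(Xt)
        QtY = Q.T @ Yt
        rss = np.einsum("ij,ij->j", Yt, Yt) - np.einsum("ij,ij->j", QtY, QtY)
        rss = np.maximum(rss, 1e-300)
        logdetV = float(np.sum(np.log1p(lam * counts)))
        logdetXtX = float(2.0 * np.sum(np.log(np.abs(np.diag(R)))))
        out[gi] = (n - p) * np.log(rss) + logdetV + logdetXtX
    return out


def _refine_lambda(F: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-region argmin of the criterion with parabolic refinement in log10."""
    idx = np.argmin(F, axis=0)
    lam = grid[idx].astype(float)
    # refine interior minima on the logarithmic part of the grid
    logs = np.full(len(grid), -np.inf)
    logs[1:] = np.log10(grid[1:])
    for r in np.nonzero((idx >= 2) & (idx <= len(grid) - 2))[0]:
        i = idx[r]
        f0, f1, f2 = F[i - 1, r], F[i, r], F[i + 1, r]
        denom = f0 - 2 * f1 + f2
        if denom > 0 and np.isfinite(logs[i - 1]):
            h = logs[i + 1] - logs[i]
            t = logs[i] + 0.5 * h * (f0 - f2) / denom
            lam[r] = 10.0 ** t
    return lam


def _fit_at_lambda(y: np.ndarray, lam: float, design: _Design, Gy_r: np.ndarray):
    """GLS fit of one region at a fixed variance ratio; returns stats."""
    groups, counts = design.groups, design.counts
    c = 1.0 - 1.0 / np.sqrt(1.0 + lam * counts)
    Xt = design.X - c[groups, None] * design.Gx[groups]
    yt = y - c[groups] * Gy_r[groups]
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (design.n - design.p)
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, sigma2, lam * sigma2


def _satterthwaite_df(design: _Design, lam: float, sigma2: float) -> np.ndarray:
    """Satterthwaite denominator df per fixed-effect coefficient."""
    X, groups = design.X, design.groups
    n, p = design.n, design.p
    Z = np.eye(len(design.counts))[groups]
    ZZt = Z @ Z.T
    tau2 = lam * sigma2
    V = sigma2 * np.eye(n) + tau2 * ZZt
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    A = np.linalg.inv(XtViX)
    P = Vi - Vi @ X @ A @ X.T @ Vi
    dV = [np.eye(n), ZZt]  # d V / d sigma2, d V / d tau2
    info = np.empty((2, 2))
    for a in range(2):
        for b in range(2):
            info[a, b] = 0.5 * np.trace(P @ dV[a] @ P @ dV[b])
    info_inv = np.linalg.pinv(info)
    dfs = np.empty(p)
    for c_idx in range(p):
        g = A[c_idx, c_idx]
        grad = np.empty(2)
        for a in range(2):
            M = A @ (X.T @ Vi @ dV[a] @ Vi @ X) @ A
            grad[a] = M[c_idx, c_idx]
        denom = float(grad @ info_inv @ grad)
        dfs[c_idx] = 2.0 * g * g / denom if denom > 0 else n - p
    return np.clip(dfs, 1.0, 10.0 * n)


_RESULT_COLUMNS = [
    "beta_age", "se_age", "p_age",
    "beta_bw0", "se_bw0", "p_bw0",
    "beta_ls", "se_ls", "p_ls",
    "region_mean", "group_var", "resid_var", "converged", "degenerate",
]


class RegionEWAS:
    """Model object for the per-region mixed-model scan.

    Parameters
    ----------
    methylome : MethylomeMatrix
        Region × sample log-scale normalized coverage.
    samples : SampleTable
        Covariates for exactly the matrix's samples (order is reconciled).
    longevity : LongevityTable
        Per strain-by-diet ages at death; the ``lifespan_stat`` (default
        median) becomes the group-level life-span covariate.
    """

    def __init__(self, methylome: MethylomeMatrix, samples: SampleTable,
                 longevity: LongevityTable, lifespan_stat: str = "median"):
        matrix_samples = list(methylome.sample_ids)
        if set(matrix_samples) != set(samples.sample_ids):
            raise ValueError("methylome samples do not match the sample table")
        order = samples.df.set_index("sample_id").loc[matrix_samples].reset_index()
        self.samples = SampleTable(order)
        self.methylome = methylome
        self.longevity = longevity
        self.design = _Design(self.samples, longevity, lifespan_stat)

    def fit(self, df_method: str = "wald", grid: np.ndarray | None = None) -> "EwasResults":
        """Run the scan over every region; one result row per region."""
        if df_method not in ("wald", "satterthwaite"):
            raise ValueError("df_method must be 'wald' or 'satterthwaite'")
        grid = _DEFAULT_GRID if grid is None else np.asarray(grid, float)
        Y = self.methylome.values  # regions x samples
        region_ids = self.methylome.region_ids
        Yt = Y.T  # samples x regions
        design = self.design
        n, p = design.n, design.p

        degenerate = np.ptp(Yt, axis=0) == 0
        active = ~degenerate
        lam_hat = np.zeros(Yt.shape[1])
        if active.any():
            F = _criterion_on_grid(Yt[:, active], design, grid)
            lam_hat[active] = _refine_lambda(F, grid)

        q = len(design.counts)
        Gy = np.zeros((q, Yt.shape[1]))
        np.add.at(Gy, design.groups, Yt)
        Gy /= design.counts[:, None]

        rows = np.empty((Yt.shape[1], 12))
        converged = np.ones(Yt.shape[1], dtype=bool)
        n_fallback = 0
        for r in range(Yt.shape[1]):
            mean_r = float(Yt[:, r].mean())
            if degenerate[r]:
                rows[r] = [0, np.nan, 1.0] * 3 + [mean_r, 0.0, 0.0]
                continue
            try:
                beta, se, sigma2, tau2 = _fit_at_lambda(
                    Yt[:, r], lam_hat[r], design, Gy[:, r]
                )
                if not (np.isfinite(beta).all() and np.isfinite(se).all()):
                    raise np.linalg.LinAlgError("non-finite fit")
            except np.linalg.LinAlgError:
                beta, se, sigma2, tau2 = _fit_at_lambda(
                    Yt[:, r], 0.0, design, Gy[:, r]
                )
                converged[r] = False
                n_fallback += 1
            z = beta / se
            if df_method == "wald":
                pvals = 2.0 * sps.norm.sf(np.abs(z))
            else:
                dfs = _satterthwaite_df(design, lam_hat[r] if converged[r] else 0.0, sigma2)
                pvals = 2.0 * sps.t.sf(np.abs(z), dfs)
            rows[r] = [
                beta[1], se[1], pvals[1],
                beta[2], se[2], pvals[2],
                beta[3], se[3], pvals[3],
                mean_r, tau2, sigma2,
            ]
        if n_fallback:
            logger.info("EWAS: %d region(s) fell back to OLS", n_fallback)
        table = pd.DataFrame(
            rows,
            index=pd.Index(region_ids, name="region_id"),
            columns=_RESULT_COLUMNS[:12],
        )
        table["converged"] = converged
        table["degenerate"] = degenerate
        return EwasResults(table, n_samples=n, n_groups=q, df_method=df_method)


@dataclass
class EwasResults:
    """Per-region coefficients, standard errors and p-values for the scan."""

    table: pd.DataFrame
    n_samples: int
    n_groups: int
    df_method: str = "wald"

    def __len__(self) -> int:
        return len(self.table)

    def bonferroni_threshold(self, family_alpha: float = 0.10) -> float:
        return bonferroni_threshold(len(self.table), family_alpha)

    def call_dmrs(self, trait: str, threshold_p: float) -> DmrSet:
        """Regions with trait p <= threshold, signed by their coefficient."""
        if trait not in TRAITS:
            raise ValueError(f"trait must be one of {TRAITS}")
        col = _TRAIT_COL[trait]
        sub = self.table[self.table[f"p_{col}"] <= threshold_p]
        df = pd.DataFrame(
            {
                "region_id": sub.index,
                "beta": sub[f"beta_{col}"].to_numpy(),
                "p": sub[f"p_{col}"].to_numpy(),
            }
        )
        df["direction"] = np.where(df["beta"] >= 0, "+", "-")
        df = df.sort_values(["p", "region_id"], kind="mergesort").reset_index(drop=True)
        return DmrSet(trait=trait, threshold_p=threshold_p, df=df)

    def summary(self, family_alpha: float = 0.10, suggestive_p: float = 1e-4) -> str:
        bonf = self.bonferroni_threshold(family_alpha)
        lines = [
            "Region-level EWAS: logRPKM ~ age + BW0 + medianLifeSpan + (1|StrainDiet)",
            f"  regions tested: {len(self.table)}   samples: {self.n_samples}   "
            f"strain-by-diet groups: {self.n_groups}",
            f"  p-values: {self.df_method}   "
            f"non-converged: {int((~self.table['converged']).sum())}",
            f"  Bonferroni ({family_alpha:g} family-wise): p <= {bonf:.3g}   "
            f"suggestive: p <= {suggestive_p:g}",
            f"  {'trait':>5} {'n_bonferroni':>13} {'n_suggestive':>13} "
            f"{'pct_positive':>13}",
        ]
        for trait in TRAITS:
            col = _TRAIT_COL[trait]
            pv = self.table[f"p_{col}"]
            sug = self.call_dmrs(trait, suggestive_p)
            npos = int((sug.df["direction"] == "+").sum())
            pct = 100.0 * npos / len(sug) if len(sug) else float("nan")
            lines.append(
                f"  {trait:>5} {int((pv <= bonf).sum()):>13} {len(sug):>13} "
                f"{pct:>12.0f}%"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.8g")


def fit_region_mixed_model(
    y, samples: SampleTable, longevity: LongevityTable, **fit_kws
) -> pd.Series:
    """Fit the mixed model at a single region; returns one result row."""
    y = np.asarray(y, dtype=float)
    mm = MethylomeMatrix(
        pd.DataFrame([y], index=["region"], columns=samples.sample_ids)
    )
    res = RegionEWAS(mm, samples, longevity).fit(**fit_kws)
    return res.table.iloc[0]


def run_ewas(
    matrix: MethylomeMatrix,
    samples: SampleTable,
    longevity: LongevityTable,
    lifespan_stat: str = "median",
    **fit_kws,
) -> EwasResults:
    """Convenience wrapper: build the model and fit every region."""
    return RegionEWAS(matrix, samples, longevity, lifespan_stat).fit(**fit_kws)


def call_dmrs(ewas: EwasResults, trait: str, threshold_p: float) -> DmrSet:
    return ewas.call_dmrs(trait, threshold_p)
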