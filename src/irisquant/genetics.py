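"""SNP QC summaries, association, epistasis, and quantitative prediction.

Genotypes are coded additively as counts of the minor allele (0/1/2) and may
be missing. The inferential battery comprises:

* per-SNP association by partial correlation of the genotype dosage and the
  phenotype after residualising both on age, sex, and population indicators,
  reported as the partial variance explained ``R^2`` (in %);
* a combined multiple regression of the phenotype on all SNPs plus the
  covariates, with adjusted ``R^2``;
* pairwise epistasis: nested linear models with and without the product term
  ``X3 = X1 * X2`` compared by an F-test, Bonferroni-corrected at a
  configurable family size; pairs in strong LD are excluded upstream;
* genotype-based prediction ``Y ~ b0 + b1*X1 + b2*X2 + b3*X3 + b4*age +
  b5*sex + b6*pop`` evaluated by repeated randomised train/holdout splits
  (default 100 repeats, 2/3 training fraction), reporting the mean holdout
  coefficient of determination and its 5%/95% quantiles.

QC statistics: minor-allele frequency, the exact conditional Hardy–Weinberg
test, composite LD as the squared dosage correlation, and Rosenberg's
informativeness for assignment (``In``, in nats) across populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "GenotypeMatrix",
    "CovariateTable",
    "SNPSummary",
    "AssociationResult",
    "InteractionResult",
    "PredictionModelSpec",
    "PredictionResult",
    "hwe_exact_test",
    "ld_r2",
    "ancestry_informativeness",
    "snp_summary",
    "snp_association",
    "combined_association",
    "interaction_test",
    "interaction_scan",
    "fit_prediction_model",
    "cross_validated_r2",
]


# ---------------------------------------------------------------- containers

@dataclass
class GenotypeMatrix:
    """n_individuals x n_snps minor-allele dosages in {0, 1, 2, NaN}."""

    values: np.ndarray
    snp_ids: tuple[str, ...]
    gene_labels: tuple[str, ...] = ()
    minor_alleles: tuple[str, ...] = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotypes must be coded 0/1/2 (minor-allele counts) or missing")
        if len(self.snp_ids) != vals.shape[1]:
            raise ValueError("snp_ids length must match the number of columns")
        self.values = vals
        self.snp_ids = tuple(self.snp_ids)
        if not self.gene_labels:
            self.gene_labels = tuple("" for _ in self.snp_ids)
        if not self.minor_alleles:
            self.minor_alleles = tuple("" for _ in self.snp_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]


@dataclass
class CovariateTable:
    """Per-individual covariates aligned with the genotype rows."""

    age: np.ndarray
    sex: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        if not (len(self.age) == len(self.sex) == len(self.population)):
            raise ValueError("covariate columns must have equal length")
        if np.any(self.age <= 0):
            raise ValueError("age must be positive")

    def __len__(self) -> int:
        return len(self.age)

    def design(self, include_population: bool = True) -> tuple[np.ndarray, list[str]]:
        """Covariate design columns (no intercept): age, sex, population dummies.

        Population enters as indicator columns with the alphabetically first
        level as the reference.
        """
        cols = [self.age, self.sex]
        names = ["age", "sex"]
        if include_population:
            levels = sorted(set(self.population))
            for level in levels[1:]:
                cols.append((self.population == level).astype(float))
                names.append(f"pop[{level}]")
        return np.column_stack(cols), names


@dataclass(frozen=True)
class SNPSummary:
    snp_id: str
    maf: float
    p_hwe: float
    in_ancestry: float
    call_rate: float


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    phenotype: str
    beta: float
    r2: float          # partial variance explained, percent
    p: float
    n: int


@dataclass(frozen=True)
class InteractionResult:
    snp_a: str
    snp_b: str
    phenotype: str
    beta3: float
    f_stat: float
    p: float
    passes_bonferroni: bool = False
    untestable: bool = False
    n: int = 0


@dataclass
class PredictionModelSpec:
    phenotype: str
    snps: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    use_age: bool = True
    use_sex: bool = True
    use_population: bool = True
    coefficients: dict | None = None
    adjusted_r2: float | None = None

    def __post_init__(self):
        snps = set(self.snps)
        for a, b in self.interactions:
            if a not in snps or b not in snps:
                raise ValueError(f"interaction ({a}, {b}) not drawn from the SNP set")


@dataclass(frozen=True)
class PredictionResult:
    spec: PredictionModelSpec
    mean_r2: float
    q05: float
    q95: float
    n_rep: int
    train_fraction: float
    seed: int
    per_repeat_r2: tuple[float, ...] = ()


# ------------------------------------------------------------------- QC ops

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Sums the probabilities, conditional on the observed allele counts, of all
    heterozygote configurations no more probable than the observed one.
    Monomorphic markers return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa   # count of the rarer allele
    if n_rare == 0:
        return 1.0
    # log-probability of each possible heterozygote count with matching parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(rare_hom + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + special.gammaln(n_rare + 1)
        + special.gammaln(2 * n - n_rare + 1)
        - special.gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def ld_r2(g_a, g_b) -> float:
    """Composite LD: squared Pearson correlation of dosages (pairwise-complete)."""
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    ok = ~(np.isnan(g_a) | np.isnan(g_b))
    a, b = g_a[ok], g_b[ok]
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("LD undefined for a constant genotype vector")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ancestry_informativeness(g, pop) -> float:
    """Rosenberg informativeness for assignment, ``In`` (nats), for a
    biallelic marker across K populations:

    ``In = sum_alleles [ -pbar log pbar + sum_pops (p_pop / K) log p_pop ]``
    with ``0 log 0 = 0`` and ``pbar`` the unweighted mean allele frequency.
    """
    g = np.asarray(g, dtype=float)
    pop = np.asarray(pop, dtype=object)
    levels = sorted(set(pop[~pd.isna(pop)]))
    freqs = []
    for level in levels:
        sel = (pop == level) & ~np.isnan(g)
        if sel.sum() == 0:
            continue
        freqs.append(g[sel].mean() / 2.0)
    if len(freqs) < 2:
        raise ValueError("need at least two populations with called genotypes")
    k = len(freqs)
    total = 0.0
    for p_vec in (np.asarray(freqs), 1.0 - np.asarray(freqs)):
        pbar = p_vec.mean()
        total += -_xlogx(pbar) + np.sum(_xlogx(p_vec)) / k
    return float(max(0.0, total))


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out if out.ndim else float(out)


def snp_summary(G: GenotypeMatrix, cov: CovariateTable) -> pd.DataFrame:
    """Per-SNP MAF, exact HWE p, ancestry informativeness, and call rate."""
    rows = []
    for j, snp in enumerate(G.snp_ids):
        g = G.values[:, j]
        called = g[~np.isnan(g)]
        call_rate = len(called) / len(g) if len(g) else 0.0
        freq = called.mean() / 2.0 if len(called) else float("nan")
        maf = min(freq, 1 - freq)
        n_aa = int(np.sum(called == 2))
        n_het = int(np.sum(called == 1))
        n_AA = int(np.sum(called == 0))
        p_hwe = hwe_exact_test(n_AA, n_het, n_aa)
        try:
            in_a = ancestry_informativeness(g, cov.population)
        except ValueError:
            in_a = float("nan")
        rows.append(
            SNPSummary(snp_id=snp, maf=float(maf), p_hwe=p_hwe,
                       in_ancestry=in_a, call_rate=call_rate)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# -------------------------------------------------------------- linear algebra

def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit; returns (coefficients, residual sum of squares)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _residualise(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def _complete(*arrays) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        ok &= ~np.isnan(a if a.ndim == 1 else a.sum(axis=1))
    return ok


# ------------------------------------------------------------- association

def snp_association(
    g,
    y,
    cov: CovariateTable | None = None,
    snp_id: str = "",
    phenotype: str = "",
    include_population: bool = True,
) -> AssociationResult:
    """Partial-correlation association of one SNP with one phenotype.

    Genotype and phenotype are residualised on [intercept, age, sex,
    population dummies]; ``r`` is the Pearson correlation of the residuals,
    ``r2 = 100 r^2``, and the p-value comes from
    ``t = r sqrt((n - 2 - k) / (1 - r^2))`` with ``k`` covariate columns.
    ``beta`` is the genotype coefficient of the equivalent full linear model.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if cov is not None:
        Z_cov, names = cov.design(include_population)
        ok = _complete(g, y, Z_cov)
        Z = np.column_stack([np.ones(ok.sum()), Z_cov[ok]])
        k = Z.shape[1] - 1
    else:
        ok = _complete(g, y)
        Z = np.ones((int(ok.sum()), 1))
        k = 0
    gg, yy = g[ok], y[ok]
    n = len(gg)
    if n <= k + 2:
        raise ValueError("too few complete observations for the covariate set")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate design is rank deficient (collinear columns)")
    rg = _residualise(gg, Z)
    ry = _residualise(yy, Z)
    if np.std(rg) == 0 or np.std(ry) == 0:
        raise ValueError("constant residuals; association undefined")
    r = float(np.corrcoef(rg, ry)[0, 1])
    df = n - 2 - k
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    X = np.column_stack([Z, gg])
    beta, _ = _ols(X, yy)
    return AssociationResult(
        snp_id=snp_id, phenotype=phenotype, beta=float(beta[-1]),
        r2=100.0 * r * r, p=max(p, np.finfo(float).tiny), n=n,
    )


def combined_association(
    G: GenotypeMatrix,
    y,
    cov: CovariateTable | None = None,
    phenotype: str = "",
    include_population: bool = True,
    collinear_r2: float = 1.0 - 1e-10,
) -> tuple[pd.DataFrame, float]:
    """Multiple regression of the phenotype on all SNPs plus covariates.

    Perfectly collinear SNPs (dosage r² at or above ``collinear_r2``) are
    dropped with a warning, keeping the first of each pair. Returns the
    per-SNP conditional results and the model's adjusted R² (percent).
    """
    y = np.asarray(y, dtype=float)
    keep: list[int] = []
    for j in range(len(G.snp_ids)):
        dup = False
        for i in keep:
            r2 = ld_r2(G.values[:, i], G.values[:, j])
            if np.isfinite(r2) and r2 >= collinear_r2:
                warnings.warn(
                    f"SNP {G.snp_ids[j]} is collinear with {G.snp_ids[i]} (r2={r2:.3f}); dropped"
                )
                dup = True
                break
        if not dup:
            keep.append(j)
    Gk = G.values[:, keep]
    names = [G.snp_ids[j] for j in keep]
    if cov is not None:
        Z_cov, _ = cov.design(include_population)
        ok = _complete(y, Z_cov) & ~np.isnan(Gk).any(axis=1)
        X = np.column_stack([np.ones(ok.sum()), Z_cov[ok], Gk[ok]])
        k_cov = Z_cov.shape[1]
    else:
        ok = _complete(y) & ~np.isnan(Gk).any(axis=1)
        X = np.column_stack([np.ones(ok.sum()), Gk[ok]])
        k_cov = 0
    yy = y[ok]
    n, p_cols = X.shape
    beta, rss = _ols(X, yy)
    tss = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = n - p_cols
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0))
    rows = []
    for idx, name in enumerate(names):
        col = 1 + k_cov + idx
        b = beta[col]
        if se[col] > 0:
            t = b / se[col]
            pv = float(2 * stats.t.sf(abs(t), dof))
        else:
            pv = 0.0 if b != 0 else 1.0
        rows.append({"snp_id": name, "phenotype": phenotype, "beta": float(b),
                     "t_p": max(pv, np.finfo(float).tiny), "n": n})
    adj_r2 = 100.0 * (1.0 - (1.0 - r2) * (n - 1) / (n - p_cols))
    return pd.DataFrame(rows), float(adj_r2)


# --------------------------------------------------------------- epistasis

def interaction_test(
    g_a,
    g_b,
    y,
    cov: CovariateTable | None = None,
    snp_a: str = "",
    snp_b: str = "",
    phenotype: str = "",
    include_population: bool = True,
) -> InteractionResult:
    """Nested-model F-test for a SNP×SNP product-term effect.

    Null: ``Y ~ b0 + b1 X1 + b2 X2 + covariates``; full adds ``b3 X3`` with
    ``X3 = X1 * X2``. ``F = (RSS0 - RSS1) / (RSS1 / (n - p1))`` on 1 df.
    Degenerate product terms (collinear with the main effects) are flagged
    untestable rather than raising.
    """
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    y = np.asarray(y, dtype=float)
    if cov is not None:
        Z_cov, _ = cov.design(include_population)
        ok = _complete(g_a, g_b, y, Z_cov)
        Zc = Z_cov[ok]
    else:
        ok = _complete(g_a, g_b, y)
        Zc = np.empty((int(ok.sum()), 0))
    a, b, yy = g_a[ok], g_b[ok], y[ok]
    n = len(yy)
    x3 = a * b
    base = [np.ones(n), a, b] + ([Zc[:, i] for i in range(Zc.shape[1])])
    X0 = np.column_stack(base)
    X1 = np.column_stack(base + [x3])
    if np.linalg.matrix_rank(X1) < X1.shape[1] or np.std(a) == 0 or np.std(b) == 0:
        return InteractionResult(snp_a, snp_b, phenotype, float("nan"), float("nan"),
                                 float("nan"), untestable=True, n=n)
    _, rss0 = _ols(X0, yy)
    beta1, rss1 = _ols(X1, yy)
    dof = n - X1.shape[1]
    if rss1 <= 0:
        f = float("inf")
        p = 0.0
    else:
        f = max(0.0, (rss0 - rss1) / (rss1 / dof))
        p = float(stats.f.sf(f, 1, dof))
    return InteractionResult(
        snp_a=snp_a, snp_b=snp_b, phenotype=phenotype,
        beta3=float(beta1[-1]), f_stat=f, p=max(p, np.finfo(float).tiny), n=n,
    )


def interaction_scan(
    G: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    cov: CovariateTable | None = None,
    ld_exclusion_threshold: float = 0.8,
    alpha: float = 0.05,
    family_size: int | None = None,
    include_population: bool = True,
) -> list[InteractionResult]:
    """All SNP pairs × phenotypes, excluding pairs in strong LD.

    Pairs with dosage r² above ``ld_exclusion_threshold`` are skipped
    entirely (their product term carries no independent signal). Results are
    Bonferroni-flagged at ``alpha / family_size`` (default family size =
    number of tests performed) and sorted by p-value.
    """
    snps = G.snp_ids
    pairs = []
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            r2 = ld_r2(G.values[:, i], G.values[:, j])
            if np.isfinite(r2) and r2 > ld_exclusion_threshold:
                warnings.warn(
                    f"pair ({snps[i]}, {snps[j]}) excluded: LD r2={r2:.3f}"
                )
                continue
            pairs.append((i, j))
    results = []
    for pheno in phenotypes.columns:
        y = phenotypes[pheno].to_numpy(float)
        for i, j in pairs:
            results.append(
                interaction_test(
                    G.values[:, i], G.values[:, j], y, cov,
                    snp_a=snps[i], snp_b=snps[j], phenotype=pheno,
                    include_population=include_population,
                )
            )
    m = family_size if family_size is not None else max(1, len(results))
    if family_size is not None and family_size < len(results):
        raise ValueError("family_size must be at least the number of tests performed")
    flagged = [
        InteractionResult(
            r.snp_a, r.snp_b, r.phenotype, r.beta3, r.f_stat, r.p,
            passes_bonferroni=(not r.untestable) and r.p < alpha / m,
            untestable=r.untestable, n=r.n,
        )
        for r in results
    ]
    flagged.sort(key=lambda r: (np.inf if np.isnan(r.p) else r.p))
    return flagged


# -------------------------------------------------------------- prediction

def _design_for_spec(
    spec: PredictionModelSpec, G: GenotypeMatrix, cov: CovariateTable | None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    cols = [np.ones(G.n)]
    names = ["intercept"]
    for snp in spec.snps:
        cols.append(G.column(snp))
        names.append(snp)
    for a, b in spec.interactions:
        cols.append(G.column(a) * G.column(b))
        names.append(f"{a}x{b}")
    if cov is not None:
        if spec.use_age:
            cols.append(cov.age)
            names.append("age")
        if spec.use_sex:
            cols.append(cov.sex)
            names.append("sex")
        if spec.use_population:
            levels = sorted(set(cov.population))
            for level in levels[1:]:
                cols.append((cov.population == level).astype(float))
                names.append(f"pop[{level}]")
    X = np.column_stack(cols)
    ok = ~np.isnan(X).any(axis=1)
    return X, names, ok


def fit_prediction_model(
    spec: PredictionModelSpec,
    G: GenotypeMatrix,
    y,
    cov: CovariateTable | None = None,
) -> PredictionModelSpec:
    """OLS fit of the prediction design; stores coefficients and adjusted R² (%)."""
    y = np.asarray(y, dtype=float)
    X, names, ok = _design_for_spec(spec, G, cov)
    ok &= ~np.isnan(y)
    X, yy = X[ok], y[ok]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("prediction design is rank deficient")
    beta, rss = _ols(X, yy)
    n, p_cols = X.shape
    tss = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_cols)
    spec.coefficients = dict(zip(names, (float(b) for b in beta)))
    spec.adjusted_r2 = 100.0 * adj
    return spec


def cross_validated_r2(
    spec: PredictionModelSpec,
    G: GenotypeMatrix,
    y,
    cov: CovariateTable | None = None,
    n_rep: int = 100,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> PredictionResult:
    """Repeated randomised train/holdout evaluation of a prediction model.

    Each repeat draws a seeded random split, fits on the training part, and
    scores ``R² = 100 (1 - SS_res / SS_tot)`` on the holdout. Reports the
    mean and the 5%/95% quantiles across repeats. Holdouts with zero
    phenotype variance are skipped with a warning.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    y = np.asarray(y, dtype=float)
    X, _, ok = _design_for_spec(spec, G, cov)
    ok &= ~np.isnan(y)
    X, yy = X[ok], y[ok]
    n = len(yy)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_rep):
        perm = rng.permutation(n)
        tr, ho = perm[:n_train], perm[n_train:]
        beta, _ = _ols(X[tr], yy[tr])
        pred = X[ho] @ beta
        ss_tot = float(np.sum((yy[ho] - yy[ho].mean()) ** 2))
        if ss_tot == 0:
            warnings.warn("holdout phenotype variance is zero; repeat skipped")
            continue
        ss_res = float(np.sum((yy[ho] - pred) ** 2))
        scores.append(100.0 * (1.0 - ss_res / ss_tot))
    scores_arr = np.asarray(scores)
    return PredictionResult(
        spec=spec,
        mean_r2=float(scores_arr.mean()),
        q05=float(np.quantile(scores_arr, 0.05)),
        q95=float(np.quantile(scores_arr, 0.95)),
        n_rep=n_rep,
        train_fraction=train_fraction,
        seed=seed,
        per_repeat_r2=tuple(scores),
    )
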