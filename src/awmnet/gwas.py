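"""Mixed-linear-model association (MLMA) of allele dosages with quantitative traits.

The model for one trait and one tested variant is

    y = 1 mu + x b + u + e,    u ~ N(0, G sigma2_u),   e ~ N(0, I sigma2_e)

with y the pre-adjusted phenotypes, x the allele dosages in [0, 2], and G the
VanRaden genomic relationship matrix.  Variance components are estimated once
per trait by REML on the null model (b = 0) and held fixed while every variant
is tested by generalized least squares with a two-sided Wald test — the
protocol of GCTA's ``--mlma``.  A single eigendecomposition of G is reused for
the REML profile likelihood and for all per-variant GLS solves.

``MlmaGwas`` is the model object (data in), ``fit()`` returns ``GwasResults``
(estimates, standard errors, p-values, variance components, ``summary()``),
and the downstream QTL/AWM stages hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import optimize, special

from .simulate import GenotypeMatrix, TraitPanel

if TYPE_CHECKING:  # pragma: no cover
    from .awm import AwMatrix
    from .qtl import QtlRegion

__all__ = [
    "Grm",
    "VarianceComponents",
    "MlmaGwas",
    "GwasResults",
    "compute_grm",
    "fit_null_model",
    "run_gwas",
    "bonferroni_threshold",
    "wald_neglog10p",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class Grm:
    """Genomic relationship matrix with the count of variants that built it."""

    matrix: np.ndarray
    n_variants_used: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("GRM diagonal must be positive")


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates for the null model y = 1 mu + u + e of one trait."""

    sigma2_u: float
    sigma2_e: float
    mu: float
    loglik: float
    converged: bool

    @property
    def h2(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else 0.0


def compute_grm(g: GenotypeMatrix, variant_subset: np.ndarray | None = None) -> Grm:
    """VanRaden GRM: G = Z Z' / s with Z the 2p-centered dosages, s = sum 2p(1-p).

    Monomorphic variants are skipped and excluded from s.  ``variant_subset``
    optionally restricts the computation to a boolean mask or index array of
    variants (e.g. an HD-chip proxy panel).
    """
    D = g.dosages
    if variant_subset is not None:
        D = D[:, variant_subset]
    if D.shape[0] < 2:
        raise ValueError("GRM needs at least 2 individuals")
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants are monomorphic; GRM is unusable")
    Dp = D[:, poly]
    pp = p[poly]
    Z = Dp - 2.0 * pp
    s = float(np.sum(2.0 * pp * (1.0 - pp)))
    G = (Z @ Z.T) / s
    return Grm(matrix=G, n_variants_used=int(poly.sum()))


class _GrmEigen:
    """Cached eigendecomposition of a GRM, shared by REML and the GLS scan."""

    def __init__(self, grm: Grm):
        w, U = np.linalg.eigh(grm.matrix)
        self.d = np.clip(w, 0.0, None)
        self.U = U
        self.ones_t = U.T @ np.ones(U.shape[0])

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.U.T @ a


def _reml_profile(h2: float, d: np.ndarray, yt: np.ndarray, ot: np.ndarray) -> tuple[float, float, float]:
    """Restricted log-likelihood profiled over (mu, total variance) at fixed h2.

    Returns (loglik up to an additive constant, mu_hat, sigma2_total_hat).
    """
    n = len(yt)
    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    a11 = float(np.sum(w * ot * ot))
    mu = float(np.sum(w * ot * yt) / a11)
    r = yt - mu * ot
    q = float(np.sum(w * r * r))
    s2 = q / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(s2) + float(np.sum(np.log(v))) + np.log(a11) + (n - 1))
    return ll, mu, s2


def fit_null_model(y: np.ndarray, grm: Grm | _GrmEigen) -> VarianceComponents:
    """REML variance components for y = 1 mu + u + e via 1-D search on h2.

    The heritability ratio h2 = sigma2_u / (sigma2_u + sigma2_e) is profiled
    on [0, 1 - 1e-6] with bounded Brent search after one eigendecomposition of
    G; boundary estimates (h2 = 0) are allowed.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    eig = grm if isinstance(grm, _GrmEigen) else _GrmEigen(grm)
    if len(y) != len(eig.d):
        raise ValueError("phenotype length does not match GRM order")
    yt = eig.rotate(y)
    ot = eig.ones_t

    res = optimize.minimize_scalar(
        lambda h: -_reml_profile(h, eig.d, yt, ot)[0],
        bounds=(0.0, 1.0 - 1e-6),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll, mu, s2 = _reml_profile(h2, eig.d, yt, ot)
    # snap to the boundary when the optimum is numerically at zero
    ll0, mu0, s20 = _reml_profile(0.0, eig.d, yt, ot)
    if ll0 >= ll:
        h2, ll, mu, s2 = 0.0, ll0, mu0, s20
    return VarianceComponents(
        sigma2_u=h2 * s2,
        sigma2_e=(1.0 - h2) * s2,
        mu=mu,
        loglik=ll,
        converged=bool(res.success),
    )


def wald_neglog10p(effect, se):
    """-log10 of the two-sided Wald normal p-value, computed on the log scale.

    Uses log(erfc) so the result stays finite for arbitrarily large |effect/se|
    (the strongest dairy QTL reach -log10 P in the hundreds).
    """
    effect = np.asarray(effect, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    t = np.abs(effect / se)
    # 2 * Phi(-t) = erfc(t / sqrt(2))
    log_p = special.log_ndtr(-t) + np.log(2.0)
    return -log_p / _LN10


def neglog10p_to_p(neglog10p) -> np.ndarray:
    """p-values from -log10 p, floored at the smallest positive float."""
    p = np.power(10.0, -np.asarray(neglog10p, dtype=float))
    return np.maximum(p, np.finfo(float).tiny)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Genome-wide significance threshold alpha / n_tests and its -log10."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p_thr = alpha / n_tests
    return p_thr, -np.log10(p_thr)


def _gls_scan(
    eig: _GrmEigen, X: np.ndarray, y: np.ndarray, vc: VarianceComponents
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant GLS with V = G s2u + I s2e fixed; returns (b, se, degenerate)."""
    Vdiag = vc.sigma2_u * eig.d + vc.sigma2_e
    w = 1.0 / Vdiag
    Xt = eig.U.T @ X
    yt = eig.rotate(y)
    ot = eig.ones_t
    a11 = float(np.sum(w * ot * ot))
    a1y = float(np.sum(w * ot * yt))
    c = (w * ot) @ Xt
    sxx = w @ (Xt**2) - c**2 / a11
    sxy = (w * yt) @ Xt - c * a1y / a11
    scale = max(float(np.mean(w @ (Xt**2))), 1.0)
    degenerate = sxx <= 1e-12 * scale
    sxx_safe = np.where(degenerate, 1.0, sxx)
    b = np.where(degenerate, 0.0, sxy / sxx_safe)
    se = np.where(degenerate, np.inf, np.sqrt(1.0 / sxx_safe))
    return b, se, degenerate


class MlmaGwas:
    """Single-trait mixed-linear-model GWAS over every variant x trait pair.

    Parameters
    ----------
    panel : TraitPanel
        Pre-adjusted phenotypes, one column per trait.
    genotypes : GenotypeMatrix
        Allele dosages in [0, 2].
    grm : Grm, optional
        Genomic relationship matrix; computed from all variants when omitted
        (``grm_variant_subset`` restricts it to a proxy panel).
    """

    def __init__(
        self,
        panel: TraitPanel,
        genotypes: GenotypeMatrix,
        grm: Grm | None = None,
        grm_variant_subset: np.ndarray | None = None,
    ):
        if panel.values.shape[0] != genotypes.n_individuals:
            raise ValueError("phenotype and genotype sample counts differ")
        if panel.individuals and panel.individuals != list(genotypes.individuals):
            raise ValueError("sample identifiers of phenotypes and genotypes disagree")
        self.panel = panel
        self.genotypes = genotypes
        self.grm = grm if grm is not None else compute_grm(genotypes, grm_variant_subset)

    @classmethod
    def from_dataframe(
        cls, phenotypes: pd.DataFrame, genotypes: GenotypeMatrix, key_trait: str | None = None
    ) -> "MlmaGwas":
        """Build from a sample-indexed phenotype DataFrame (columns = traits)."""
        pheno = phenotypes.loc[list(genotypes.individuals)]
        panel = TraitPanel(
            values=pheno.to_numpy(dtype=float),
            traits=list(pheno.columns),
            key_trait=key_trait or pheno.columns[0],
            individuals=list(genotypes.individuals),
        )
        return cls(panel, genotypes)

    def fit(self, traits: list[str] | None = None) -> "GwasResults":
        traits = traits or list(self.panel.traits)
        eig = _GrmEigen(self.grm)
        X = self.genotypes.dosages
        vcs: dict[str, VarianceComponents] = {}
        eff = np.empty((X.shape[1], len(traits)))
        se = np.empty_like(eff)
        nlp = np.empty_like(eff)
        degen = np.zeros_like(eff, dtype=bool)
        for j, t in enumerate(traits):
            y = self.panel.column(t)
            vc = fit_null_model(y, eig)
            vcs[t] = vc
            b, s, dg = _gls_scan(eig, X, y, vc)
            eff[:, j], se[:, j], degen[:, j] = b, s, dg
            with np.errstate(invalid="ignore"):
                nlp[:, j] = np.where(dg, 0.0, wald_neglog10p(b, np.where(dg, 1.0, s)))
        ids = self.genotypes.variants["id"]
        return GwasResults(
            model=self,
            effects=pd.DataFrame(eff, index=ids, columns=traits),
            se=pd.DataFrame(se, index=ids, columns=traits),
            neglog10p=pd.DataFrame(nlp, index=ids, columns=traits),
            degenerate=pd.DataFrame(degen, index=ids, columns=traits),
            variance_components=vcs,
        )


class GwasResults:
    """Per-variant x trait MLMA estimates with downstream-analysis entry points."""

    def __init__(
        self,
        model: MlmaGwas,
        effects: pd.DataFrame,
        se: pd.DataFrame,
        neglog10p: pd.DataFrame,
        degenerate: pd.DataFrame,
        variance_components: dict[str, VarianceComponents],
    ):
        self.model = model
        self.effects = effects
        self.se = se
        self.neglog10p = neglog10p
        self.degenerate = degenerate
        self.variance_components = variance_components

    @property
    def traits(self) -> list[str]:
        return list(self.effects.columns)

    @property
    def pvalues(self) -> pd.DataFrame:
        return pd.DataFrame(
            neglog10p_to_p(self.neglog10p.to_numpy()),
            index=self.neglog10p.index,
            columns=self.neglog10p.columns,
        )

    @property
    def n_tests(self) -> int:
        return int(self.effects.size)

    def bonferroni(self, alpha: float = 0.05) -> tuple[float, float]:
        """Study-wide Bonferroni threshold over all variant x trait tests."""
        return bonferroni_threshold(self.n_tests, alpha)

    def to_frame(self, trait: str) -> pd.DataFrame:
        """Per-trait summary statistics joined to variant metadata."""
        v = self.model.genotypes.variants.set_index("id")
        out = v.copy()
        out["effect"] = self.effects[trait]
        out["se"] = self.se[trait]
        out["neglog10p"] = self.neglog10p[trait]
        out["p"] = neglog10p_to_p(out["neglog10p"].to_numpy())
        return out.reset_index()

    def call_qtl_regions(
        self,
        trait: str,
        neglog10_threshold: float | None = None,
        merge_bp: int = 1_000_000,
    ) -> "list[QtlRegion]":
        from .qtl import call_qtl_regions

        if neglog10_threshold is None:
            neglog10_threshold = self.bonferroni()[1]
        return call_qtl_regions(self.to_frame(trait), neglog10_threshold, merge_bp=merge_bp)

    def build_awm(self, ann, key_trait: str | None = None, **kwargs) -> "AwMatrix":
        from .awm import build_awm

        return build_awm(self, ann, key_trait or self.model.panel.key_trait, **kwargs)

    def summary(self) -> str:
        p_thr, nlp_thr = self.bonferroni()
        lines = [
            "Mixed-linear-model GWAS results",
            f"  individuals: {self.model.genotypes.n_individuals}"
            f"   variants: {self.model.genotypes.n_variants}   traits: {len(self.traits)}",
            f"  Bonferroni (alpha=0.05, {self.n_tests} tests): "
            f"p <= {p_thr:.3g}  (-log10 P >= {nlp_thr:.2f})",
            "",
            f"  {'trait':<14}{'sigma2_u':>10}{'sigma2_e':>10}{'h2':>8}{'n signif':>10}",
        ]
        for t in self.traits:
            vc = self.variance_components[t]
            nsig = int((self.neglog10p[t] > nlp_thr).sum())
            lines.append(
                f"  {t:<14}{vc.sigma2_u:>10.4f}{vc.sigma2_e:>10.4f}{vc.h2:>8.3f}{nsig:>10d}"
            )
        return "\n".join(lines)


def run_gwas(
    g: GenotypeMatrix,
    panel: TraitPanel,
    vc: dict[str, VarianceComponents] | None = None,
    grm: Grm | None = None,
) -> GwasResults:
    """Functional entry point: fit (or reuse) variance components and scan.

    ``vc`` may carry pre-fitted per-trait variance components; any missing
    trait is fitted on the null model first.
    """
    model = MlmaGwas(panel, g, grm=grm)
    if vc is None:
        return model.fit()
    eig = _GrmEigen(model.grm)
    traits = list(panel.traits)
    eff = np.empty((g.n_variants, len(traits)))
    se = np.empty_like(eff)
    nlp = np.empty_like(eff)
    degen = np.zeros_like(eff, dtype=bool)
    vcs = {}
    for j, t in enumerate(traits):
        y = panel.column(t)
        vcs[t] = vc.get(t) or fit_null_model(y, eig)
        b, s, dg = _gls_scan(eig, g.dosages, y, vcs[t])
        eff[:, j], se[:, j], degen[:, j] = b, s, dg
        nlp[:, j] = np.where(dg, 0.0, wald_neglog10p(b, np.where(dg, 1.0, s)))
    ids = g.variants["id"]
    return GwasResults(
        model=model,
        effects=pd.DataFrame(eff, index=ids, columns=traits),
        se=pd.DataFrame(se, index=ids, columns=traits),
        neglog10p=pd.DataFrame(nlp, index=ids, columns=traits),
        degenerate=pd.DataFrame(degen, index=ids, columns=traits),
        variance_components=vcs,
    )
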