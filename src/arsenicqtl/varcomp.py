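"""Maximum-likelihood variance components on pedigrees.

The model is the standard polygenic mixed model

    y ~ N(X beta,  sigma2_g * 2*Phi  +  sigma2_q * Pi  +  sigma2_c * H  +  sigma2_e * I)

with the additive component keyed to the relationship matrix 2*Phi, an
optional QTL component keyed to a locus-specific IBD matrix Pi, an optional
household (shared environment) component, and an i.i.d. residual.  Fitting is
by ML (not REML): fixed effects are profiled out analytically at every
variance evaluation, variances are optimized on the log scale with three
deterministic starts, and boundary estimates (a component pinned at zero) are
detected by a likelihood-equivalent pinned refit so that likelihood-ratio
statistics have an exact point mass at zero.

Heritability is h2 = sigma2_g / (sum of all fitted variance components), and
its standard error comes from the delta method on the inverse numerical
observed information of the variance parameters.  The test of h2 = 0 uses the
boundary-corrected 1/2:1/2 mixture of a point mass at zero and chi-square(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2

from .pedigree import Pedigree, kinship_matrix

__all__ = [
    "VarCompModel",
    "VarCompFit",
    "MixtureTestResult",
    "VarCompError",
    "log_likelihood",
    "fit_ml",
    "heritability_test",
    "lod_from_lrt",
    "lrt_from_lod",
    "stratified_heritability",
]

LOGL_TOL = 1e-6          # likelihood-equivalence tolerance for boundary pinning
BOUNDARY_TRIGGER = 0.02  # fraction of phenotypic variance below which pinning is tried


class VarCompError(RuntimeError):
    """Numerical or optimization failure in a variance-component fit."""


@dataclass
class VarCompModel:
    """Trait, fixed-effect design, and named covariance components.

    ``components`` maps names (e.g. ``"additive"``, ``"qtl"``, ``"household"``)
    to symmetric PSD n x n matrices; the i.i.d. residual component is always
    present implicitly.  ``blocks`` optionally lists index arrays of
    independent groups (pedigree connected components); the likelihood then
    factorizes over blocks, which is exact and much faster.
    """

    y: np.ndarray
    X: np.ndarray
    components: dict[str, np.ndarray]
    blocks: list[np.ndarray] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.shape[0]
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != n:
            raise VarCompError("design matrix rows do not match trait length")
        for name, mat in self.components.items():
            if mat.shape != (n, n):
                raise VarCompError(f"component {name!r} has shape {mat.shape}, expected {(n, n)}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def block_views(self):
        """Per-block (y, X, {name: M}) triples; one full block if unblocked."""
        if self.blocks is None:
            return [(self.y, self.X, self.components)]
        out = []
        for idx in self.blocks:
            mats = {k: m[np.ix_(idx, idx)] for k, m in self.components.items()}
            out.append((self.y[idx], self.X[idx], mats))
        return out

    def grouped(self):
        """Blocks batched by size for vectorized (LAPACK-batched) likelihoods.

        Returns a list of dicts with stacked arrays: y (B, nb), X (B, nb, p),
        and each component as (B, nb, nb).  Computed once and cached.
        """
        if getattr(self, "_grouped", None) is not None:
            return self._grouped
        blocks = self.blocks if self.blocks is not None else [np.arange(self.n)]
        by_size: dict[int, list[np.ndarray]] = {}
        for idx in blocks:
            by_size.setdefault(len(idx), []).append(idx)
        groups = []
        for nb, idxs in by_size.items():
            ys = np.stack([self.y[i] for i in idxs])
            xs = np.stack([self.X[i] for i in idxs])
            comps = {k: np.stack([m[np.ix_(i, i)] for i in idxs])
                     for k, m in self.components.items()}
            groups.append({"nb": nb, "y": ys, "X": xs, "comps": comps,
                           "eye": np.eye(nb)})
        self._grouped = groups
        return groups


@dataclass
class VarCompFit:
    """Result of an ML variance-component fit."""

    variances: dict[str, float]          # includes "residual"
    beta: np.ndarray
    loglik: float
    h2: float
    h2_se: float | None
    converged: bool
    boundary: dict[str, bool]
    n: int
    message: str = ""
    vcov_variances: np.ndarray | None = field(default=None, repr=False)

    def variance(self, name: str) -> float:
        return self.variances[name]


@dataclass
class MixtureTestResult:
    """Boundary LRT against the 1/2:1/2 chi-square(1) + point-mass null."""

    lrt: float
    p_value: float
    df: str = "0.5*chi2(1) + 0.5*point-mass(0)"


def _profile_loglik(model: VarCompModel, variances: dict[str, float]):
    """Profile log-likelihood: beta maximized analytically by GLS.

    Returns (logL, beta).  Raises VarCompError if the implied covariance is
    not positive definite.  Blocks of equal size are processed as one
    LAPACK-batched Cholesky, which is what makes dense scans and null
    simulations affordable.
    """
    n = model.n
    p = model.X.shape[1]
    logdet = 0.0
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    for grp in model.grouped():
        B = grp["y"].shape[0]
        omega = variances["residual"] * grp["eye"]
        for name, sig in variances.items():
            if name != "residual" and sig != 0.0:
                omega = omega + sig * grp["comps"][name]
        shared = omega.ndim == 2  # same covariance for every block in the group
        if shared:
            omega = omega[None, ...]
        try:
            chol = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as exc:
            raise VarCompError(
                "covariance matrix not positive definite at "
                f"variances {variances}"
            ) from exc
        diag = np.diagonal(chol, axis1=-2, axis2=-1)
        logdet += 2.0 * float(np.sum(np.log(diag))) * (B if shared else 1)
        rhs = np.concatenate([grp["y"][..., None], grp["X"]], axis=-1)
        z = np.linalg.solve(chol, rhs)  # batched lower-triangular solve
        zy = z[..., 0]
        zx = z[..., 1:]
        xtx += np.einsum("bni,bnj->ij", zx, zx)
        xty += np.einsum("bni,bn->i", zx, zy)
        yty += float(np.sum(zy * zy))
    try:
        beta = linalg.solve(xtx, xty, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise VarCompError("fixed-effect normal equations are singular "
                           "(rank-deficient design)") from exc
    quad = yty - beta @ xty
    logl = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    return logl, beta


def log_likelihood(model: VarCompModel, variances: dict[str, float],
                   beta: np.ndarray | None = None) -> float:
    """Multivariate-normal log-likelihood at given variances (and beta).

    With ``beta=None`` the GLS profile value is returned, i.e. beta maximized
    out; otherwise the likelihood is evaluated at the supplied coefficients.
    """
    if beta is None:
        return _profile_loglik(model, variances)[0]
    resid = model.y - model.X @ beta
    shifted = VarCompModel(resid, np.zeros((model.n, 1)), model.components, model.blocks)
    # zero design: profile beta is 0, likelihood reduces to the centered form
    logl, _ = _profile_loglik_centered(shifted, variances)
    return logl


def _profile_loglik_centered(model, variances):
    n = model.n
    logdet = 0.0
    quad = 0.0
    for yb, _, mats in model.block_views():
        omega = variances["residual"] * np.eye(yb.shape[0])
        for name, sig in variances.items():
            if name != "residual" and sig != 0.0:
                omega = omega + sig * mats[name]
        try:
            c, low = linalg.cho_factor(omega, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise VarCompError(
                f"covariance matrix not positive definite at variances {variances}"
            ) from exc
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        zy = linalg.solve_triangular(c, yb, lower=low, check_finite=False)
        quad += zy @ zy
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad), np.zeros(model.X.shape[1])


def _starts(names: list[str], var_p: float) -> list[dict[str, float]]:
    """Three deterministic initializations spreading phenotypic variance."""
    k = len(names) - 1  # non-residual free components
    starts = []
    for resid_frac in (1.0 / len(names), 0.1, 0.9):
        s = {}
        for nm in names:
            if nm == "residual":
                s[nm] = resid_frac * var_p
            else:
                s[nm] = (1.0 - resid_frac) / max(k, 1) * var_p
        starts.append(s)
    return starts


def fit_ml(model: VarCompModel, fixed: dict[str, float] | None = None) -> VarCompFit:
    """Maximize the likelihood over non-negative variance components.

    ``fixed`` pins named components at given values (typically 0 for a null
    model).  Free variances are optimized as log-variances by L-BFGS-B from
    three deterministic starts; afterwards any free component estimated below
    ``BOUNDARY_TRIGGER`` of the phenotypic variance is refit pinned at zero
    and the pinned solution is kept whenever it costs less than ``LOGL_TOL``
    log-likelihood units, flagging that component as a boundary estimate.
    """
    fixed = dict(fixed or {})
    free = [nm for nm in list(model.components) + ["residual"] if nm not in fixed]
    if "residual" in fixed and fixed["residual"] < 0:
        raise VarCompError("residual variance cannot be negative")
    var_p = float(np.var(model.y))
    if not np.isfinite(model.y).all():
        raise VarCompError("trait contains non-finite values")
    if var_p <= 0:
        raise VarCompError("trait has zero variance")

    lo, hi = np.log(1e-8 * var_p), np.log(1e3 * var_p)

    def run(free_names, fixed_map):
        """Optimize over free_names; remaining components held at fixed_map."""

        def assemble(theta):
            v = dict(fixed_map)
            for nm, t in zip(free_names, theta):
                v[nm] = float(np.exp(t))
            return v

        if not free_names:
            logl, beta = _profile_loglik(model, dict(fixed_map))
            return dict(fixed_map), logl, beta, True, ""
        best = None
        for start in _starts(free_names, var_p):
            theta0 = np.array([np.log(max(start.get(nm, 0.5 * var_p), 1e-8 * var_p))
                               for nm in free_names])

            def nll(theta):
                try:
                    logl, _ = _profile_loglik(model, assemble(theta))
                except VarCompError:
                    return 1e10
                return -logl

            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B",
                bounds=[(lo, hi)] * len(free_names),
                options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
        v = assemble(best.x)
        logl, beta = _profile_loglik(model, v)
        return v, logl, beta, bool(best.success), str(best.message)

    variances, logl, beta, ok, msg = run(free, fixed)

    # boundary detection: pin near-zero components when likelihood-equivalent
    pinned_fixed = dict(fixed)
    changed = True
    while changed:
        changed = False
        candidates = [nm for nm in free
                      if nm not in pinned_fixed and nm != "residual"
                      and variances[nm] < BOUNDARY_TRIGGER * var_p]
        for nm in sorted(candidates, key=lambda k: variances[k]):
            trial_fixed = dict(pinned_fixed)
            trial_fixed[nm] = 0.0
            trial_free = [f for f in free if f not in trial_fixed]
            try:
                v_t, logl_t, beta_t, ok_t, msg_t = run(trial_free, trial_fixed)
            except VarCompError:
                continue
            if logl_t >= logl - LOGL_TOL:
                pinned_fixed = trial_fixed
                variances, logl, beta, ok, msg = v_t, logl_t, beta_t, ok_t, msg_t
                changed = True
                break
    boundary = {nm: (nm in pinned_fixed and nm not in fixed) for nm in variances}

    if not ok:
        msg = msg or "optimizer did not report convergence"
        warnings.warn(f"variance-component fit flagged: {msg}", RuntimeWarning)

    # heritability over the fitted components
    total = sum(variances.values())
    sigma_g = variances.get("additive", 0.0)
    h2 = sigma_g / total if total > 0 else np.nan

    free_final = [nm for nm in free if nm not in pinned_fixed]
    any_boundary = any(boundary.get(nm, False) for nm in variances)
    h2_se = None
    vcov = None
    if free_final and not any_boundary and "additive" in variances and "additive" in free_final:
        h2_se, vcov = _h2_se_delta(model, variances, pinned_fixed, free_final, sigma_g, total)

    return VarCompFit(
        variances=dict(variances),
        beta=beta,
        loglik=float(logl),
        h2=float(h2),
        h2_se=h2_se,
        converged=ok,
        boundary=boundary,
        n=model.n,
        message=msg,
        vcov_variances=vcov,
    )


def _h2_se_delta(model, variances, fixed, free_names, sigma_g, total):
    """Delta-method SE of h2 from the numerical observed information."""
    x0 = np.array([variances[nm] for nm in free_names])
    steps = np.maximum(1e-4 * np.abs(x0), 1e-6 * total)

    def f(x):
        v = dict(fixed)
        v.update({nm: xi for nm, xi in zip(free_names, x)})
        try:
            return _profile_loglik(model, v)[0]
        except VarCompError:
            return -np.inf

    k = len(free_names)
    hess = np.zeros((k, k))
    f0 = f(x0)
    for a in range(k):
        for b in range(a, k):
            ea = np.eye(k)[a] * steps[a]
            eb = np.eye(k)[b] * steps[b]
            if a == b:
                val = (f(x0 + ea) - 2 * f0 + f(x0 - ea)) / steps[a] ** 2
            else:
                val = (
                    f(x0 + ea + eb) - f(x0 + ea - eb) - f(x0 - ea + eb) + f(x0 - ea - eb)
                ) / (4 * steps[a] * steps[b])
            hess[a, b] = hess[b, a] = val
    info = -hess
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        return None, None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None, None
    # h2 = sigma_g / (sigma_g + others + fixed); gradient wrt free variances
    grad = np.zeros(k)
    for idx, nm in enumerate(free_names):
        if nm == "additive":
            grad[idx] = (total - sigma_g) / total**2
        else:
            grad[idx] = -sigma_g / total**2
    var_h2 = float(grad @ cov @ grad)
    if var_h2 < 0:
        return None, None
    return float(np.sqrt(var_h2)), cov


def heritability_test(fit_full: VarCompFit, fit_null: VarCompFit) -> MixtureTestResult:
    """Boundary LRT of sigma2_g = 0 with the 1/2:1/2 mixture null.

    p = 0.5 * P(chi2_1 >= LRT) for LRT > 0 and exactly 0.5 at LRT = 0 (the
    point mass).  A full-model likelihood below the null beyond tolerance is
    an optimization failure, never silently clamped.
    """
    lrt = 2.0 * (fit_full.loglik - fit_null.loglik)
    if lrt < -1e-6:
        raise VarCompError(
            f"full-model log-likelihood {fit_full.loglik:.6f} is below the null "
            f"{fit_null.loglik:.6f}; optimization failed"
        )
    lrt = max(lrt, 0.0)
    p = 0.5 if lrt == 0.0 else 0.5 * float(chi2.sf(lrt, df=1))
    return MixtureTestResult(lrt=float(lrt), p_value=p)


def lod_from_lrt(lrt: float) -> float:
    """LOD = LRT / (2 ln 10), the log10 likelihood ratio."""
    if lrt < 0:
        raise ValueError(f"likelihood-ratio statistic must be >= 0, got {lrt}")
    return lrt / (2.0 * np.log(10.0))


def lrt_from_lod(lod: float) -> float:
    if lod < 0:
        raise ValueError(f"LOD must be >= 0, got {lod}")
    return lod * 2.0 * np.log(10.0)


def polygenic_model(y, ped: Pedigree, X=None, household: bool = False,
                    ids=None) -> VarCompModel:
    """Assemble the polygenic model for a trait on a pedigree.

    ``ids`` optionally restricts/reorders individuals (default: all, pedigree
    order).  Components: additive = 2*Phi (+ household indicator if asked);
    blocks are the pedigree's connected components.
    """
    from .pedigree import household_matrix

    kin = kinship_matrix(ped)
    if ids is None:
        sel = np.arange(len(ped))
    else:
        sel = np.array([ped.index(str(i)) for i in ids])
    a = kin.relationship[np.ix_(sel, sel)]
    comps = {"additive": a}
    if household:
        comps["household"] = household_matrix(ped)[np.ix_(sel, sel)]
    pos = {s: k for k, s in enumerate(sel)}
    blocks = []
    for fam in ped.families():
        idx = [pos[i] for i in fam if i in pos]
        if idx:
            blocks.append(np.array(sorted(idx)))
    return VarCompModel(y=np.asarray(y, float), X=X, components=comps, blocks=blocks)


def stratified_heritability(y, ped: Pedigree, strata, X=None,
                            household: bool = False):
    """Independent polygenic fits per stratum plus overall.

    Kinship is computed on the full pedigree, then sub-set per stratum, so
    within-stratum relatives connected through out-of-stratum ancestors keep
    their relatedness; related pairs that span strata are simply dropped and
    tallied in the result.  A stratum with no related pairs is flagged
    not-estimable instead of fitted.
    """
    y = np.asarray(y, float)
    strata = np.asarray([str(s) for s in strata])
    kin = kinship_matrix(ped)
    out: dict[str, dict] = {}

    def fit_subset(mask, label):
        idx = np.flatnonzero(mask)
        a = kin.relationship[np.ix_(idx, idx)]
        off = a[np.triu_indices(len(idx), k=1)]
        if not np.any(off > 0):
            out[label] = {"estimable": False, "n": int(len(idx)),
                          "reason": "no related pairs in stratum"}
            return
        comps = {"additive": a}
        if household:
            from .pedigree import household_matrix
            comps["household"] = household_matrix(ped)[np.ix_(idx, idx)]
        xb = None if X is None else np.atleast_2d(np.asarray(X, float))[idx]
        model = VarCompModel(y[idx], xb, comps, blocks=_blocks_from_matrix(a))
        full = fit_ml(model)
        null = fit_ml(model, fixed={"additive": 0.0})
        test = heritability_test(full, null)
        out[label] = {"estimable": True, "n": int(len(idx)), "fit": full,
                      "null": null, "test": test}

    fit_subset(np.ones(len(y), bool), "overall")
    for s in sorted(set(strata)):
        fit_subset(strata == s, s)

    # tally related pairs spanning strata (dropped from every per-stratum fit)
    ii, jj = np.triu_indices(len(ped), k=1)
    rel = kin.phi[ii, jj] > 0
    cross = int(np.sum(rel & (strata[ii] != strata[jj])))
    out["cross_stratum_pairs_dropped"] = cross
    return out


def _blocks_from_matrix(a: np.ndarray) -> list[np.ndarray]:
    """Connected components of the nonzero pattern of a covariance matrix."""
    import networkx as nx

    g = nx.from_numpy_array((np.abs(a) > 0).astype(int))
    return [np.array(sorted(c)) for c in nx.connected_components(g)]
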