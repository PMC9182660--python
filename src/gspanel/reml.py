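"""Restricted maximum likelihood for trial variance-component models.

The models fitted here all have the form

    y = X beta + sum_r Z_r u_r + e,   u_r ~ N(0, sigma2_r I),  e ~ N(0, sigma2_e I)

where every random factor except (at most) one *crossed* factor is nested in
a grouping partition of the observations — in the trial setting the groups
are environments, the nested factors are genotype-by-environment, replicate
and incomplete block, and the crossed factor is the genotype (line), which
appears in every environment.

This structure makes the scaled covariance ``V/sigma2_e = A + gamma_g Z Z'``
with ``A`` block-diagonal by group, so every likelihood evaluation reduces to
small dense Cholesky factorizations per group plus one Woodbury correction of
dimension equal to the number of lines.  The REML criterion is profiled over
``sigma2_e`` and optimized over the log variance ratios ``log gamma_r`` with
bounded quasi-Newton (L-BFGS-B), optionally polished by Nelder-Mead.  A ratio
driven to the lower bound is truncated to zero, which implements the
convention of constraining negative variance estimates to a floor of zero
during (not after) optimization.

Fixed effects may be given either as one dense matrix (small ``p``) or in
*groupwise* form — a list of per-group column blocks, as in a cell-means
parameterization of genotype-by-environment — in which case ``X' V^-1 X`` is
block-diagonal and is never materialized as a single dense matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["VarCompModel", "RemlFit", "RemlError", "fit_reml"]

_LOG_GAMMA_LO = np.log(1e-6)
_LOG_GAMMA_HI = np.log(1e8)
_ZERO_GAMMA = 2e-6  # ratios at the boundary are reported as exactly zero


class RemlError(RuntimeError):
    """REML optimization failed to converge."""


def _safe_cho(A: np.ndarray):
    """Cholesky with a tiny escalating ridge for numerically semidefinite
    matrices (arises only in degenerate variance-ratio limits)."""
    try:
        return cho_factor(A, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        scale = max(np.trace(A) / max(len(A), 1), 1e-300)
        for eps in (1e-12, 1e-10, 1e-8):
            try:
                return cho_factor(A + eps * scale * np.eye(len(A)),
                                  lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                continue
        raise


def _codes(values) -> tuple[np.ndarray, int]:
    """Integer-encode a factor; returns (codes, n_levels)."""
    _, codes = np.unique(np.asarray(values), return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if len(codes) else 0


@dataclass
class RemlFit:
    """Result of a REML fit."""

    sigma2: dict  # term name -> variance component; includes "residual"
    beta: np.ndarray  # fixed-effect estimates (concatenated groupwise blocks)
    neg2_reml: float
    n: int
    p: int
    grad_norm: float
    model: "VarCompModel" = field(repr=False)

    @property
    def gammas(self) -> np.ndarray:
        s2e = self.sigma2["residual"]
        return np.array([self.sigma2[t] / s2e for t in self.model.term_names])

    def cov_sigma2(self) -> tuple[list, np.ndarray]:
        """Asymptotic covariance of the variance components by numeric REML
        information (central-difference Hessian of the unprofiled criterion).

        Components estimated at the zero boundary are excluded; returns the
        (names, covariance) pair for the interior components plus residual.
        """
        names = [t for t in self.model.term_names if self.sigma2[t] > 0]
        names.append("residual")
        x0 = np.array([self.sigma2[t] for t in names])
        zero_terms = [t for t in self.model.term_names if self.sigma2[t] == 0]

        def f(x):
            sig = dict(zip(names, x))
            for t in zero_terms:
                sig[t] = 0.0
            return self.model.neg2_reml_at(sig)

        k = len(x0)
        h = np.maximum(1e-4 * np.abs(x0), 1e-7)
        H = np.empty((k, k))
        f0 = f(x0)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            for j in range(i):
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
        cov = 2.0 * np.linalg.pinv(H)
        return names, cov


class VarCompModel:
    """One variance-component model instance (data plus design).

    Parameters
    ----------
    y : response vector.
    groups : per-observation group labels (the block-diagonal partition;
        pass a constant for a single-group model).
    nested : mapping of factor name to per-observation labels; every level
        must occur in a single group.
    crossed : optional ``(name, labels)`` for the one factor crossed with the
        groups (the line/genotype term).
    X : dense fixed-effect matrix (defaults to an intercept), or ``None``
        together with ``x_blocks``.
    x_blocks : optional groupwise fixed effects: list (one entry per group,
        in group code order) of either dense matrices over that group's rows
        or 1-D integer level codes, which are treated as one-hot indicator
        blocks (cell-means coding) and get a dedicated fast path.
    cell_factor : optional name of the nested factor whose levels are the
        (crossed level x group) cells; enables the structured fast path.
    """

    def __init__(self, y, groups, nested=None, crossed=None, X=None,
                 x_blocks=None, cell_factor=None):
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        gcodes, G = _codes(groups)
        self.group_idx = [np.flatnonzero(gcodes == j) for j in range(G)]
        self.nested = {}
        for name, labels in (nested or {}).items():
            codes, q = _codes(labels)
            if q > 1:  # single-level factors are unidentifiable; drop
                self.nested[name] = codes
        self.crossed_name = None
        self.q_g = 0
        if crossed is not None:
            cname, clabels = crossed
            ccodes, qg = _codes(clabels)
            self.crossed_name = cname
            self.crossed_codes = ccodes
            self.q_g = qg
        self.term_names = list(self.nested) + (
            [self.crossed_name] if self.crossed_name else []
        )
        # structured fast path: a nested factor whose levels are exactly the
        # (crossed level x group) cells lets each group inverse be a cheap
        # double Woodbury instead of a dense Cholesky
        self.cell_factor = None
        if cell_factor is not None and self.crossed_name is not None \
                and cell_factor in self.nested:
            self._fast_groups = []
            valid = True
            for idx in self.group_idx:
                cc = self.crossed_codes[idx]
                u_glob, c_local = np.unique(cc, return_inverse=True)
                fc = self.nested[cell_factor][idx]
                n_pairs = len(set(zip(c_local.tolist(), fc.tolist())))
                if not (n_pairs == len(u_glob) == len(np.unique(fc))):
                    valid = False
                    break
                counts = np.bincount(c_local).astype(float)
                self._fast_groups.append((idx, u_glob, c_local, counts))
            if valid:
                self.cell_factor = cell_factor
        if x_blocks is not None:
            if self.crossed_name is not None:
                raise ValueError("groupwise fixed effects require no crossed factor")
            self._x_onehot = all(np.asarray(b).ndim == 1 for b in x_blocks)
            if self._x_onehot:
                # blocks given as integer level codes: one-hot indicators
                self._x_codes = []
                for b in x_blocks:
                    codes = np.asarray(b, dtype=np.intp)
                    self._x_codes.append((codes, int(codes.max()) + 1))
                self.x_blocks = x_blocks
                self.p = sum(L for _, L in self._x_codes)
            else:
                self.x_blocks = [np.atleast_2d(np.asarray(b, dtype=float))
                                 for b in x_blocks]
                self.p = sum(b.shape[1] for b in self.x_blocks)
        else:
            self.X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
            self.x_blocks = None
            self._x_onehot = False
            self.p = self.X.shape[1]
        self.n = n
        if self.n - self.p < 1:
            raise RemlError(
                "no residual degrees of freedom: the fixed design saturates "
                "the data"
            )

    # ------------------------------------------------------------------
    def _profile_eval(self, gammas, want_beta=False):
        """Evaluate the sigma2_e-profiled REML pieces at variance ratios
        ``gammas`` (aligned with ``term_names``).

        Returns (neg2_reml, logdetV, logdetXtVX, rss, beta|None).  A point
        where the factorizations break down numerically (extreme ratios)
        evaluates to +inf so the optimizer retreats.
        """
        try:
            return self._profile_eval_inner(gammas)
        except np.linalg.LinAlgError:
            return np.inf, np.inf, np.inf, np.nan, None

    def _profile_eval_inner(self, gammas):
        g = dict(zip(self.term_names, gammas))
        gamma_g = g.pop(self.crossed_name, 0.0) if self.crossed_name else 0.0
        n, p = self.n, self.p
        use_crossed = self.crossed_name is not None and gamma_g > 0

        if self.cell_factor is not None:
            pieces = self._accumulate_fast(g, use_crossed)
            return self._finish(*pieces, gamma_g=gamma_g, use_crossed=use_crossed)
        if self._x_onehot:
            return self._eval_onehot_blocks(g)

        logdetA = 0.0
        if self.x_blocks is None:
            XtAX = np.zeros((p, p)); XtAy = np.zeros(p)
        else:
            blk_XtAX = []; blk_XtAy = []
        ytAy = 0.0
        if use_crossed:
            M = np.zeros((self.q_g, self.q_g))
            ZtAX = np.zeros((self.q_g, p)); ZtAy = np.zeros(self.q_g)

        for j, idx in enumerate(self.group_idx):
            nj = len(idx)
            A = np.eye(nj)
            for name, gam in g.items():
                if gam <= 0:
                    continue
                cj = self.nested[name][idx]
                A += gam * (cj[:, None] == cj[None, :])
            cho = cho_factor(A, lower=True, check_finite=False)
            logdetA += 2.0 * np.log(np.diag(cho[0])).sum()

            yj = self.y[idx]
            if self.x_blocks is None:
                Xj = self.X[idx]
            else:
                Xj = self.x_blocks[j]
            rhs = [Xj, yj[:, None]]
            if use_crossed:
                Zj = np.zeros((nj, self.q_g))
                Zj[np.arange(nj), self.crossed_codes[idx]] = 1.0
                rhs.append(Zj)
            sol = cho_solve(cho, np.hstack(rhs), check_finite=False)
            pj = Xj.shape[1]
            AX, Ay = sol[:, :pj], sol[:, pj]
            if self.x_blocks is None:
                XtAX += Xj.T @ AX
                XtAy += Xj.T @ Ay
            else:
                blk_XtAX.append(Xj.T @ AX)
                blk_XtAy.append(Xj.T @ Ay)
            ytAy += yj @ Ay
            if use_crossed:
                AZ = sol[:, pj + 1:]
                M += Zj.T @ AZ
                ZtAX += Zj.T @ AX
                ZtAy += Zj.T @ Ay

        if self.x_blocks is None:
            crossed_parts = (M, ZtAX, ZtAy) if use_crossed else None
            return self._finish(logdetA, XtAX, XtAy, ytAy, crossed_parts,
                                gamma_g=gamma_g, use_crossed=use_crossed)

        # groupwise fixed effects (no crossed factor): block-diagonal GLS
        logdetXtVX = 0.0
        betas = []
        rss = ytAy
        for Bx, By in zip(blk_XtAX, blk_XtAy):
            if Bx.shape[1] == 0:
                betas.append(np.empty(0))
                continue
            choX = cho_factor(Bx, lower=True, check_finite=False)
            logdetXtVX += 2.0 * np.log(np.diag(choX[0])).sum()
            bj = cho_solve(choX, By, check_finite=False)
            betas.append(bj)
            rss -= By @ bj
        beta = np.concatenate(betas) if betas else np.empty(0)
        rss = max(rss, 1e-300)
        sigma2e = rss / (n - p)
        neg2 = ((n - p) * (np.log(sigma2e) + 1.0 + np.log(2 * np.pi))
                + logdetA + logdetXtVX)
        return neg2, logdetA, logdetXtVX, rss, beta

    # ------------------------------------------------------------------
    def _finish(self, logdetA, XtAX, XtAy, ytAy, crossed_parts, gamma_g,
                use_crossed):
        """Shared tail: crossed-factor Woodbury, GLS solve, profiled REML."""
        n, p = self.n, self.p
        logdetV = logdetA
        if use_crossed:
            M, ZtAX, ZtAy = crossed_parts
            S = M + np.eye(self.q_g) / gamma_g
            choS = _safe_cho(S)
            logdetV += (2.0 * np.log(np.diag(choS[0])).sum()
                        + self.q_g * np.log(gamma_g))
            SX = cho_solve(choS, ZtAX, check_finite=False)
            Sy = cho_solve(choS, ZtAy, check_finite=False)
            XtAX = XtAX - ZtAX.T @ SX
            XtAy = XtAy - ZtAX.T @ Sy
            ytAy = ytAy - ZtAy @ Sy

        choX = _safe_cho(XtAX)
        logdetXtVX = 2.0 * np.log(np.diag(choX[0])).sum()
        beta = cho_solve(choX, XtAy, check_finite=False)
        rss = ytAy - XtAy @ beta
        rss = max(rss, 1e-300)
        sigma2e = rss / (n - p)
        neg2 = ((n - p) * (np.log(sigma2e) + 1.0 + np.log(2 * np.pi))
                + logdetV + logdetXtVX)
        return neg2, logdetV, logdetXtVX, rss, beta

    # ------------------------------------------------------------------
    def _eval_onehot_blocks(self, g: dict):
        """Groupwise one-hot fixed effects (cell-means coding): ``X'V^-1 X``
        is diagonal minus a rank-q correction per group, so the whole
        evaluation is linear in the group size."""
        n, p = self.n, self.p
        others = {name: gam for name, gam in g.items() if gam > 0}
        logdetV = 0.0
        logdetX = 0.0
        rss = 0.0
        betas = []
        for j, idx in enumerate(self.group_idx):
            yj = self.y[idx]
            nj = len(idx)
            cx, Lj = self._x_codes[j]
            cnt = np.bincount(cx, minlength=Lj).astype(float)
            if (cnt == 0).any():
                raise RemlError("empty fixed-effect cell in groupwise design")
            Xty = np.bincount(cx, weights=yj, minlength=Lj)
            yty = yj @ yj
            logdetX_j = np.log(cnt).sum()
            if others:
                cols = []; gU = []
                for name, gam in others.items():
                    codes = self.nested[name][idx]
                    lu, lc = np.unique(codes, return_inverse=True)
                    onehot = np.zeros((nj, len(lu)))
                    onehot[np.arange(nj), lc] = 1.0
                    cols.append(onehot)
                    gU.extend([gam] * len(lu))
                U = np.hstack(cols); gU = np.array(gU)
                G = np.diag(1.0 / gU) + U.T @ U
                choG = cho_factor(G, lower=True, check_finite=False)
                logdetV += (np.log(gU).sum()
                            + 2.0 * np.log(np.diag(choG[0])).sum())
                Uty = U.T @ yj
                E = np.zeros((Lj, U.shape[1]))
                np.add.at(E, cx, U)  # X'U
                GiUty = cho_solve(choG, Uty, check_finite=False)
                XtAy = Xty - E @ GiUty
                ytAy = yty - Uty @ GiUty
                Ec = E / cnt[:, None]
                H = G - Ec.T @ E  # G - E' D^-1 E
                choH = _safe_cho(H)
                logdetX_j += (2.0 * np.log(np.diag(choH[0])).sum()
                              - 2.0 * np.log(np.diag(choG[0])).sum())
                beta_j = XtAy / cnt + Ec @ cho_solve(
                    choH, Ec.T @ XtAy, check_finite=False)
                rss += ytAy - XtAy @ beta_j
            else:
                beta_j = Xty / cnt
                rss += yty - Xty @ beta_j
            logdetX += logdetX_j
            betas.append(beta_j)
        beta = np.concatenate(betas)
        rss = max(rss, 1e-300)
        sigma2e = rss / (n - p)
        neg2 = ((n - p) * (np.log(sigma2e) + 1.0 + np.log(2 * np.pi))
                + logdetV + logdetX)
        return neg2, logdetV, logdetX, rss, beta

    # ------------------------------------------------------------------
    def _accumulate_fast(self, g: dict, use_crossed: bool):
        """Per-group accumulation via the structured double Woodbury.

        The cell factor (crossed level x group, e.g. line-by-environment) is
        absorbed analytically — its covariance contribution is diagonal on
        per-line plot groups — and the remaining nested factors (environment
        main effect, replicate, block) enter through a small dense correction.
        """
        gamma_c = g.get(self.cell_factor, 0.0)
        others = {name: gam for name, gam in g.items()
                  if name != self.cell_factor and gam > 0}
        p = self.p
        logdetA = 0.0
        XtAX = np.zeros((p, p)); XtAy = np.zeros(p); ytAy = 0.0
        if use_crossed:
            M = np.zeros((self.q_g, self.q_g))
            ZtAX = np.zeros((self.q_g, p)); ZtAy = np.zeros(self.q_g)

        for (idx, u_glob, c_local, r) in self._fast_groups:
            nj = len(idx); Lj = len(u_glob)
            w = gamma_c / (1.0 + gamma_c * r)  # per-cell shrinkage weights
            Xj = self.X[idx]; yj = self.y[idx]
            Y = np.column_stack([Xj, yj])

            def agg(mat):  # Z' mat: per-line sums over the group's plots
                out = np.zeros((Lj, mat.shape[1]))
                np.add.at(out, c_local, mat)
                return out

            ZtY = agg(Y)
            BY = Y - (w[:, None] * ZtY)[c_local]
            logdet_j = np.log1p(gamma_c * r).sum()
            ZtBY = ZtY / (1.0 + gamma_c * r)[:, None]
            D = r / (1.0 + gamma_c * r)

            if others:
                cols = []; gU = []
                for name, gam in others.items():
                    codes = self.nested[name][idx]
                    lu, lc = np.unique(codes, return_inverse=True)
                    onehot = np.zeros((nj, len(lu)))
                    onehot[np.arange(nj), lc] = 1.0
                    cols.append(onehot)
                    gU.extend([gam] * len(lu))
                U = np.hstack(cols); gU = np.array(gU)
                ZtU = agg(U)
                BU = U - (w[:, None] * ZtU)[c_local]
                G = np.diag(1.0 / gU) + U.T @ BU
                choG = cho_factor(G, lower=True, check_finite=False)
                logdet_j += (np.log(gU).sum()
                             + 2.0 * np.log(np.diag(choG[0])).sum())
                UtBY = U.T @ BY
                GiUtBY = cho_solve(choG, UtBY, check_finite=False)
                AY = BY - BU @ GiUtBY
                ZtBU = ZtU / (1.0 + gamma_c * r)[:, None]
                ZtAY = ZtBY - ZtBU @ GiUtBY
                Mcorr = ZtBU @ cho_solve(choG, ZtBU.T, check_finite=False)
            else:
                AY = BY
                ZtAY = ZtBY
                Mcorr = None

            logdetA += logdet_j
            XtAX += Xj.T @ AY[:, :p]
            XtAy += Xj.T @ AY[:, p]
            ytAy += yj @ AY[:, p]
            if use_crossed:
                if Lj == self.q_g:  # every line present: direct accumulation
                    if Mcorr is not None:
                        M -= Mcorr
                    M[np.arange(Lj), np.arange(Lj)] += D
                    ZtAX += ZtAY[:, :p]
                    ZtAy += ZtAY[:, p]
                else:
                    if Mcorr is not None:
                        M[np.ix_(u_glob, u_glob)] -= Mcorr
                    M[u_glob, u_glob] += D
                    ZtAX[u_glob] += ZtAY[:, :p]
                    ZtAy[u_glob] += ZtAY[:, p]

        crossed_parts = (M, ZtAX, ZtAy) if use_crossed else None
        return logdetA, XtAX, XtAy, ytAy, crossed_parts

    # ------------------------------------------------------------------
    def neg2_reml_at(self, sigma2: dict) -> float:
        """Unprofiled -2 restricted log-likelihood at given components."""
        s2e = sigma2["residual"]
        gam = [sigma2.get(t, 0.0) / s2e for t in self.term_names]
        _, logdetV, logdetX, rss, _ = self._profile_eval(gam)
        n, p = self.n, self.p
        return ((n - p) * (np.log(s2e) + np.log(2 * np.pi))
                + logdetV + logdetX + rss / s2e)


def fit_reml(model: VarCompModel, polish: bool = True,
             max_iter: int = 200) -> RemlFit:
    """Maximize the REML criterion over the variance ratios.

    Two heuristic starting points are tried; the better quasi-Newton solution
    is optionally polished with Nelder-Mead for tight convergence.  Raises
    :class:`RemlError` (carrying the final gradient norm) on failure.
    """
    k = len(model.term_names)
    if k == 0:  # pure fixed-effects model: closed form
        neg2, _, _, rss, beta = model._profile_eval([], want_beta=True)
        return RemlFit(
            sigma2={"residual": rss / (model.n - model.p)}, beta=beta,
            neg2_reml=neg2, n=model.n, p=model.p, grad_norm=0.0, model=model,
        )

    def f(theta):
        return model._profile_eval(np.exp(theta))[0]

    bounds = [(_LOG_GAMMA_LO, _LOG_GAMMA_HI)] * k
    starts = (np.full(k, np.log(0.3)), np.full(k, np.log(0.02)))
    start = min(starts, key=f)  # cheap screen, then one quasi-Newton run
    best = optimize.minimize(
        f, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    if best is None or not np.isfinite(best.fun):
        raise RemlError("REML optimization produced no finite objective")
    grad_norm = float(np.linalg.norm(getattr(best, "jac", np.array([np.nan]))))
    # a coordinate pinned at a bound (variance floor, or a variance ratio so
    # large the likelihood is effectively flat/unbounded) is a legitimate
    # boundary solution even when the line search reports failure
    at_bound = bool(np.any(best.x >= _LOG_GAMMA_HI - 1e-6)
                    or np.any(best.x <= _LOG_GAMMA_LO + 1e-6))
    if not best.success and not at_bound and grad_norm > 1e-3:
        raise RemlError(
            f"REML did not converge after {max_iter} iterations "
            f"(last gradient norm {grad_norm:.3e})"
        )
    theta = best.x
    if polish:
        res = optimize.minimize(
            f, theta, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-13, "maxfev": 120 * k},
        )
        if res.fun <= best.fun:
            theta = res.x

    gam = np.exp(theta)
    gam[gam <= _ZERO_GAMMA] = 0.0
    neg2, _, _, rss, beta = model._profile_eval(gam, want_beta=True)
    if not np.isfinite(neg2):
        raise RemlError("REML objective not finite at the optimizer solution")
    s2e = rss / (model.n - model.p)
    sigma2 = {t: float(g * s2e) for t, g in zip(model.term_names, gam)}
    sigma2["residual"] = float(s2e)
    return RemlFit(sigma2=sigma2, beta=beta, neg2_reml=float(neg2),
                   n=model.n, p=model.p, grad_norm=grad_norm, model=model)
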