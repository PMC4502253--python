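"""Centred, constraint-respecting parameterisation of the five models for HMC.

Every deviation block is represented by its coefficients in an orthonormal
basis of its constrained subspace (sum-to-zero for age and spatial blocks;
additionally trend-free for period and cohort blocks under the default APC
identification).  Priors are evaluated directly as
the natural-scale random-walk / BYM densities — the basis change has unit
Jacobian, so the sampled density *is* the model's likelihood-plus-prior up
to constants.  Innovation SDs are sampled on the log scale (half-normal
prior plus Jacobian).  The centred form is the right regime here: death
counts are informative enough to pin the blocks, leaving the scales with
clean near-lognormal conditionals.  Gradients are closed-form throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .adjacency import AdjacencyGraph
from .models import (
    ModelParameters,
    ModelSpec,
    centred_ramp,
    projected_rw1_basis,
)

ALPHA0_SD = 10.0
BETA0_SD = 1.0
SLOPE_SD = 10.0     # ramp coefficient of RW2 blocks (log-mortality age
                    # profiles have slopes of order 10 on a unit-norm ramp)
OMEGA0_SD = 2.0     # logit-scale mean of the cohort age weights
DRIFT_SD = 1.0      # Lee-Carter period drift


class InitialisationError(RuntimeError):
    """The posterior is not finite at the chain's initial point."""


def _sum_zero_basis(n: int) -> np.ndarray:
    """Orthonormal (n, n-1) basis of the sum-to-zero subspace."""
    full = np.eye(n) - 1.0 / n
    u_mat, s_vals, _ = np.linalg.svd(full)
    return u_mat[:, : n - 1]


def _diff_matrix(n: int, order: int) -> np.ndarray:
    d = np.diff(np.eye(n), n=order, axis=0)
    return d


class ModelTransform:
    """Latent-vector layout, log posterior and gradient for one model."""

    def __init__(self, spec: ModelSpec, data, graph: AdjacencyGraph):
        if graph.n_units != spec.n_districts:
            raise ValueError("graph does not match n_districts")
        self.spec = spec
        self.deaths = np.asarray(data.deaths, dtype=float)
        self.pop = np.asarray(data.population, dtype=float)
        if self.deaths.shape != (spec.n_districts, spec.n_ages, spec.n_years):
            raise ValueError("data shape does not match spec dimensions")
        self.log_pop = np.log(self.pop)

        n_a, n_t, n_s, n_c = spec.n_ages, spec.n_years, spec.n_districts, spec.n_cohorts
        self.n_a, self.n_t, self.n_s, self.n_c = n_a, n_t, n_s, n_c
        self.t = spec.t_centred
        with np.errstate(divide="ignore"):
            self.log_abs_t = np.where(self.t == 0.0, 0.0, np.log(np.abs(self.t)))
        self.cidx = spec.cohort_idx

        # age blocks: sum-zero basis; smoothness matrix per rw order
        self.ramp_a = centred_ramp(n_a)
        self.U_a = _sum_zero_basis(n_a)
        self.M_a = _diff_matrix(n_a, spec.rw_order_age) @ self.U_a
        self.P_a = self.M_a.T @ self.M_a  # penalty quad form in coefficients
        self.k_a = n_a - spec.rw_order_age  # increment count of the block
        self.ramp_coef_a = self.ramp_a @ self.U_a  # slope functional (RW2 only)

        # period block: constrained subspace basis, RW penalty per order.
        # With trend_constrained the subspace is orthogonal to {1, ramp} and
        # the RW density is the projected one (computed through the penalty
        # quad form, whose rank drops accordingly).
        self.ramp_t = centred_ramp(n_t)
        if spec.trend_constrained:
            b_t = projected_rw1_basis(n_t, 1)
            self.U_t = b_t / np.linalg.norm(b_t, axis=0)
        else:
            self.U_t = _sum_zero_basis(n_t)
        self.M_t = _diff_matrix(n_t, spec.rw_order_time) @ self.U_t
        self.P_t = self.M_t.T @ self.M_t
        # sigma-scaled dimensions: RW2 excludes the affine direction (own prior
        # when unconstrained, absent when constrained); RW1 keeps the full rank
        self.k_t = n_t - 2 if spec.rw_order_time == 2 else self.U_t.shape[1]
        self.ramp_coef_t = self.ramp_t @ self.U_t

        # cohort block: constrained subspace basis, RW1 penalty
        if spec.has_cohort and n_c >= 3:
            if spec.trend_constrained:
                b_c = projected_rw1_basis(n_c, 1)
                self.U_c = b_c / np.linalg.norm(b_c, axis=0)
            else:
                self.U_c = _sum_zero_basis(n_c)
            self.M_c = _diff_matrix(n_c, 1) @ self.U_c
            self.P_c = self.M_c.T @ self.M_c
            self.k_c = self.U_c.shape[1]
        else:
            self.U_c = np.zeros((n_c, 0))
            self.P_c = np.zeros((0, 0))
            self.k_c = 0

        # logit cohort-weight block (model 4): sum-zero basis, RW1 penalty
        self.U_w = _sum_zero_basis(n_a)
        self.M_w = _diff_matrix(n_a, 1) @ self.U_w
        self.P_w = self.M_w.T @ self.M_w

        # spatial: Laplacian eigenbasis; marginal BYM prior on the sum u+v
        if n_s > 1:
            q = graph.laplacian()
            vals, vecs = np.linalg.eigh(q)
            keep = vals > 1e-8 * max(vals.max(), 1.0)
            if keep.sum() < n_s - 1:
                raise ValueError("adjacency graph must be connected for the ICAR prior")
            self.icar_eigvals = vals[keep]
            self.icar_eigvecs = vecs[:, keep]
        else:
            self.icar_eigvals = np.zeros(0)
            self.icar_eigvecs = np.zeros((1, 0))

        # Lee-Carter period index: sum-zero basis, RW1-with-drift penalty
        self.U_k = _sum_zero_basis(n_t)
        self.M_k = _diff_matrix(n_t, 1) @ self.U_k

        self.tau = spec.hyper_scale
        self._build_layout()

    # ------------------------------------------------------------------
    def _build_layout(self) -> None:
        spec = self.spec
        entries: list[tuple[str, int]] = []
        if spec.model_id == 5:
            entries += [("a0", 1), ("c_a", self.n_a - 1), ("ls_a", 1)]
            entries += [("c_b", self.n_a - 1), ("ls_b", 1)]
            entries += [("drift", 1), ("c_k", self.n_t - 1), ("ls_k", 1)]
        else:
            entries += [("alpha0", 1), ("beta0", 1)]
            entries += [("c_alpha", self.n_a - 1), ("ls_alpha", 1)]
            entries += [("c_beta", self.n_a - 1), ("ls_beta", 1)]
            entries += [("c_gamma", self.U_t.shape[1]), ("ls_gamma", 1)]
            if spec.model_id == 2:
                entries += [("ltheta", 1)]
            if spec.has_cohort:
                entries += [("c_phi", self.U_c.shape[1]), ("ls_phi", 1)]
            if spec.model_id == 4:
                entries += [("omega0", 1), ("c_omega", self.n_a - 1), ("ls_omega", 1)]
        if self.n_s > 1:
            entries += [("c_w", self.n_s - 1), ("ls_u", 1), ("ls_v", 1)]
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in entries:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.dim = pos

    def _get(self, psi: np.ndarray, name: str) -> np.ndarray:
        return psi[self.slices[name]]

    def _scalar(self, psi: np.ndarray, name: str, default: float = 0.0) -> float:
        if name not in self.slices:
            return default
        return float(psi[self.slices[name]][0])

    def _sigma(self, psi: np.ndarray, name: str) -> float:
        # clipped to keep exp() finite while warmup explores log-scale space
        return float(np.exp(np.clip(self._scalar(psi, name), -30.0, 30.0)))

    # ------------------------------------------------------------------
    def natural(self, psi: np.ndarray) -> ModelParameters:
        """Natural-scale parameters of a single latent vector.

        The spatial slot ``u_spatial`` holds the *total* BYM effect w = u + v
        (the split is recovered afterwards by conditional simulation);
        ``v_spatial`` is zero, so likelihood computations are unchanged.
        """
        spec = self.spec
        params = ModelParameters.zeros(spec)
        sigmas: dict[str, float] = {}
        if self.n_s > 1:
            su = self._sigma(psi, "ls_u")
            sv = self._sigma(psi, "ls_v")
            params.u_spatial = self.icar_eigvecs @ self._get(psi, "c_w")
            params.v_spatial = np.zeros(self.n_s)
            sigmas.update({"spatial_u": su, "spatial_v": sv})
        else:
            sigmas.update({"spatial_u": 1.0, "spatial_v": 1.0})

        if spec.model_id == 5:
            params.lc_level = self._scalar(psi, "a0") + self.U_a @ self._get(psi, "c_a")
            params.lc_loading = 1.0 / self.n_a + self.U_a @ self._get(psi, "c_b")
            params.lc_period = self.U_k @ self._get(psi, "c_k")
            params.lc_drift = self._scalar(psi, "drift")
            sigmas.update(
                {
                    "lc_level": self._sigma(psi, "ls_a"),
                    "lc_loading": self._sigma(psi, "ls_b"),
                    "lc_period": self._sigma(psi, "ls_k"),
                }
            )
            params.sigmas = sigmas
            return params

        params.alpha0 = self._scalar(psi, "alpha0")
        params.beta0 = self._scalar(psi, "beta0")
        params.alpha_age = self.U_a @ self._get(psi, "c_alpha")
        params.beta_age = self.U_a @ self._get(psi, "c_beta")
        params.gamma_period = self.U_t @ self._get(psi, "c_gamma")
        sigmas.update(
            {
                "age_level": self._sigma(psi, "ls_alpha"),
                "age_slope": self._sigma(psi, "ls_beta"),
                "period": self._sigma(psi, "ls_gamma"),
            }
        )
        if spec.model_id == 2:
            params.theta = float(np.exp(self._scalar(psi, "ltheta")))
        if spec.has_cohort:
            params.phi_cohort = self.U_c @ self._get(psi, "c_phi")
            sigmas["cohort"] = self._sigma(psi, "ls_phi")
        if spec.model_id == 4:
            omega = self._scalar(psi, "omega0") + self.U_w @ self._get(psi, "c_omega")
            params.w_age = expit(omega)
            sigmas["cohort_weight"] = self._sigma(psi, "ls_omega")
        params.sigmas = sigmas
        return params

    # ------------------------------------------------------------------
    def logp_grad(self, psi: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior (up to a constant) and its gradient."""
        spec = self.spec
        grad = np.zeros(self.dim)
        params = self.natural(psi)

        from .models import linear_predictor_array  # local to avoid cycle at import

        eta = linear_predictor_array(params, spec)
        log_mu = self.log_pop + eta
        with np.errstate(over="ignore", invalid="ignore"):
            mu = np.exp(log_mu)
            lp = float(np.sum(self.deaths * log_mu - mu))
        if not np.isfinite(lp):
            return -np.inf, grad
        g_cell = self.deaths - mu

        def add(name: str, value) -> None:
            grad[self.slices[name]] += value

        def scale_prior(name: str, sigma: float) -> None:
            # half-normal prior on sigma, sampled as log sigma (Jacobian incl.)
            nonlocal lp
            lp += -0.5 * (sigma / self.tau) ** 2 + np.log(sigma)
            add(name, -((sigma / self.tau) ** 2) + 1.0)

        def smooth_block(cname: str, lsname: str, g_block, pen, k: int, sigma: float):
            """Gaussian smoothness penalty |M c|^2 / sigma^2 with k increments."""
            nonlocal lp
            c = self._get(psi, cname)
            quad = float(c @ pen @ c)
            lp += -0.5 * quad / sigma**2 - k * np.log(sigma)
            add(cname, g_block - (pen @ c) / sigma**2)
            add(lsname, quad / sigma**2 - k)
            scale_prior(lsname, sigma)

        # ---- spatial (all models): marginal BYM prior in eigen coordinates
        g_s = g_cell.sum(axis=(1, 2))
        if self.n_s > 1:
            su = params.sigmas["spatial_u"]
            sv = params.sigmas["spatial_v"]
            c_w = self._get(psi, "c_w")
            var_w = su**2 / self.icar_eigvals + sv**2
            lp += float(np.sum(-0.5 * c_w**2 / var_w - 0.5 * np.log(var_w)))
            add("c_w", self.icar_eigvecs.T @ g_s - c_w / var_w)
            dvar_u = su**2 / self.icar_eigvals
            dvar_v = np.full_like(var_w, sv**2)
            for lsname, dvar in (("ls_u", dvar_u), ("ls_v", dvar_v)):
                add(lsname, float(np.sum((c_w**2 / var_w**2 - 1.0 / var_w) * dvar)))
            scale_prior("ls_u", su)
            scale_prior("ls_v", sv)

        g_a = g_cell.sum(axis=(0, 2))
        g_t = g_cell.sum(axis=(0, 1))
        g_at = g_cell.sum(axis=0)

        if spec.model_id == 5:
            sa = params.sigmas["lc_level"]
            sb = params.sigmas["lc_loading"]
            sk = params.sigmas["lc_period"]
            a0 = self._scalar(psi, "a0")
            lp += -0.5 * (a0 / ALPHA0_SD) ** 2
            add("a0", float(g_a.sum()) - a0 / ALPHA0_SD**2)
            # level: RW2 penalty + slope prior
            smooth_block("c_a", "ls_a", self.U_a.T @ g_a, self.P_a, self.k_a, sa)
            slope = float(self.ramp_coef_a @ self._get(psi, "c_a"))
            lp += -0.5 * (slope / SLOPE_SD) ** 2
            add("c_a", -self.ramp_coef_a * slope / SLOPE_SD**2)
            # loading: RW1 penalty around the uniform value
            g_b = (g_at * params.lc_period[None, :]).sum(axis=1)
            m1 = _diff_matrix(self.n_a, 1) @ self.U_a
            smooth_block("c_b", "ls_b", self.U_a.T @ g_b, m1.T @ m1, self.n_a - 1, sb)
            # period index: RW1 with drift
            g_k = (g_at * params.lc_loading[:, None]).sum(axis=0)
            c_k = self._get(psi, "c_k")
            drift = params.lc_drift
            incr = self.M_k @ c_k
            resid = incr - drift
            lp += float(np.sum(-0.5 * resid**2 / sk**2)) - (self.n_t - 1) * np.log(sk)
            lp += -0.5 * (drift / DRIFT_SD) ** 2
            add("c_k", self.U_k.T @ g_k - self.M_k.T @ resid / sk**2)
            add("drift", float(resid.sum()) / sk**2 - drift / DRIFT_SD**2)
            add("ls_k", float(resid @ resid) / sk**2 - (self.n_t - 1))
            scale_prior("ls_k", sk)
            return lp, grad

        # ---- models 1-4
        if spec.model_id == 2:
            g_cov = np.sign(self.t) * np.abs(self.t) ** params.theta
        else:
            g_cov = self.t
        g_b = (g_at * g_cov[None, :]).sum(axis=1)

        alpha0, beta0 = params.alpha0, params.beta0
        lp += -0.5 * (alpha0 / ALPHA0_SD) ** 2 - 0.5 * (beta0 / BETA0_SD) ** 2
        add("alpha0", float(g_a.sum()) - alpha0 / ALPHA0_SD**2)
        add("beta0", float(g_b.sum()) - beta0 / BETA0_SD**2)

        s_al = params.sigmas["age_level"]
        s_be = params.sigmas["age_slope"]
        s_ga = params.sigmas["period"]
        smooth_block("c_alpha", "ls_alpha", self.U_a.T @ g_a, self.P_a, self.k_a, s_al)
        smooth_block("c_beta", "ls_beta", self.U_a.T @ g_b, self.P_a, self.k_a, s_be)
        if spec.rw_order_age == 2:
            for cname, sd in (("c_alpha", SLOPE_SD), ("c_beta", SLOPE_SD)):
                slope = float(self.ramp_coef_a @ self._get(psi, cname))
                lp += -0.5 * (slope / sd) ** 2
                add(cname, -self.ramp_coef_a * slope / sd**2)

        smooth_block("c_gamma", "ls_gamma", self.U_t.T @ g_t, self.P_t, self.k_t, s_ga)
        if spec.rw_order_time == 2:
            slope = float(self.ramp_coef_t @ self._get(psi, "c_gamma"))
            lp += -0.5 * (slope / SLOPE_SD) ** 2
            add("c_gamma", -self.ramp_coef_t * slope / SLOPE_SD**2)

        if spec.model_id == 2:
            ltheta = self._scalar(psi, "ltheta")
            h = np.where(self.t == 0.0, 0.0, g_cov * self.log_abs_t)
            trend = params.beta0 + params.beta_age
            d_theta = float(trend @ (g_at @ h))
            lp += -0.5 * (ltheta / spec.theta_prior_sd) ** 2
            add("ltheta", params.theta * d_theta - ltheta / spec.theta_prior_sd**2)

        if spec.has_cohort:
            s_ph = params.sigmas["cohort"]
            if spec.model_id == 4:
                weighted = params.w_age[:, None] * g_at
            else:
                weighted = g_at
            g_c = np.bincount(self.cidx.ravel(), weights=weighted.ravel(), minlength=self.n_c)
            smooth_block("c_phi", "ls_phi", self.U_c.T @ g_c, self.P_c, self.k_c, s_ph)

        if spec.model_id == 4:
            s_om = params.sigmas["cohort_weight"]
            omega0 = self._scalar(psi, "omega0")
            g_w = (g_at * params.phi_cohort[self.cidx]).sum(axis=1)
            d_omega = g_w * params.w_age * (1.0 - params.w_age)
            lp += -0.5 * (omega0 / OMEGA0_SD) ** 2
            add("omega0", float(d_omega.sum()) - omega0 / OMEGA0_SD**2)
            smooth_block(
                "c_omega", "ls_omega", self.U_w.T @ d_omega, self.P_w, self.n_a - 1, s_om
            )

        return lp, grad

    # ------------------------------------------------------------------
    def prior_precision(self, psi: np.ndarray) -> np.ndarray:
        """Dense prior Hessian (quadratic terms) at ``psi``'s scales."""
        params = self.natural(psi)
        prec = np.zeros((self.dim, self.dim))

        def put(name: str, block: np.ndarray) -> None:
            sl = self.slices[name]
            prec[sl, sl] += block

        def put_diag(name: str, value) -> None:
            sl = self.slices[name]
            prec[sl, sl] += np.diag(np.atleast_1d(value) * np.ones(sl.stop - sl.start))

        if self.n_s > 1:
            su, sv = params.sigmas["spatial_u"], params.sigmas["spatial_v"]
            put("c_w", np.diag(1.0 / (su**2 / self.icar_eigvals + sv**2)))
        if self.spec.model_id == 5:
            put_diag("a0", 1.0 / ALPHA0_SD**2)
            put("c_a", self.P_a / params.sigmas["lc_level"] ** 2
                + np.outer(self.ramp_coef_a, self.ramp_coef_a))
            m1 = _diff_matrix(self.n_a, 1) @ self.U_a
            put("c_b", (m1.T @ m1) / params.sigmas["lc_loading"] ** 2)
            put("c_k", (self.M_k.T @ self.M_k) / params.sigmas["lc_period"] ** 2)
            put_diag("drift", 1.0 / DRIFT_SD**2)
        else:
            put_diag("alpha0", 1.0 / ALPHA0_SD**2)
            put_diag("beta0", 1.0 / BETA0_SD**2)
            ramp_quad = np.outer(self.ramp_coef_a, self.ramp_coef_a)
            extra = ramp_quad if self.spec.rw_order_age == 2 else 0.0
            put("c_alpha", self.P_a / params.sigmas["age_level"] ** 2 + extra)
            put("c_beta", self.P_a / params.sigmas["age_slope"] ** 2 + extra)
            extra_t = (np.outer(self.ramp_coef_t, self.ramp_coef_t)
                       if self.spec.rw_order_time == 2 else 0.0)
            put("c_gamma", self.P_t / params.sigmas["period"] ** 2 + extra_t)
            if self.spec.has_cohort:
                put("c_phi", self.P_c / params.sigmas["cohort"] ** 2)
            if self.spec.model_id == 4:
                put_diag("omega0", 1.0 / OMEGA0_SD**2)
                put("c_omega", self.P_w / params.sigmas["cohort_weight"] ** 2)
        # log-scale and remaining scalar coordinates: unit curvature floor
        prec[np.diag_indices_from(prec)] += 1.0
        return prec

    def fisher_matrix(self, psi: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Dense expected information at ``psi``: J^T diag(mu) J + prior Hessian.

        ``J = d eta / d psi`` by central differences (exact up to rounding for
        the linear coordinates).  Used as a fixed HMC mass matrix; it whitens
        the strong likelihood-induced correlations between age, period,
        cohort and spatial blocks that a diagonal mass cannot remove.
        """
        from .models import linear_predictor_array

        params = self.natural(psi)
        mu = (self.pop * np.exp(linear_predictor_array(params, self.spec))).ravel()
        jac = np.empty((mu.size, self.dim))
        for i in range(self.dim):
            p_hi = psi.copy()
            p_hi[i] += h
            p_lo = psi.copy()
            p_lo[i] -= h
            eta_hi = linear_predictor_array(self.natural(p_hi), self.spec)
            eta_lo = linear_predictor_array(self.natural(p_lo), self.spec)
            jac[:, i] = (eta_hi - eta_lo).ravel() / (2.0 * h)
        fisher = (jac * mu[:, None]).T @ jac
        fisher += self.prior_precision(psi)
        return 0.5 * (fisher + fisher.T)

    # ------------------------------------------------------------------
    def initial_point(self) -> np.ndarray:
        """Data-driven start: empirical log rates for level terms, zeros elsewhere.

        A +0.5 continuity correction keeps zero-death cells finite.
        """
        psi = np.zeros(self.dim)
        lr = np.log((self.deaths + 0.5) / self.pop)
        profile = lr.mean(axis=(0, 2))
        level = float(profile.mean())
        prof_dev = profile - level
        lr_t = lr.mean(axis=(0, 1))
        denom = float(self.t @ self.t)
        slope_t = float(self.t @ lr_t) / denom if denom > 0 else 0.0

        def set_(name: str, value) -> None:
            if name in self.slices:
                psi[self.slices[name]] = value

        if self.spec.model_id == 5:
            set_("a0", level)
            set_("c_a", self.U_a.T @ prof_dev)
            set_("ls_a", np.log(0.3))
            set_("ls_b", np.log(1e-2))
            set_("drift", slope_t * self.n_a)
            set_("c_k", self.U_k.T @ ((lr_t - lr_t.mean()) * self.n_a))
            set_("ls_k", np.log(5e-2))
        else:
            set_("alpha0", level)
            set_("beta0", slope_t)
            set_("c_alpha", self.U_a.T @ prof_dev)
            set_("ls_alpha", np.log(0.3))
            set_("ls_beta", np.log(5e-3))
            set_("ls_gamma", np.log(2e-2))
            set_("ls_phi", np.log(3e-2))
            set_("omega0", 1.0)
            set_("ls_omega", np.log(0.3))
        if self.n_s > 1:
            district_dev = lr.mean(axis=(1, 2)) - level
            set_("c_w", self.icar_eigvecs.T @ district_dev)
            set_("ls_u", np.log(0.1))
            set_("ls_v", np.log(5e-2))
        return psi
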