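"""The joint path model: fecundity + survival + imputation in one posterior.

The model operates on a full individual-by-year grid: one record per
individual per breeding year from its first capture to the last year the
bird could have been alive, whether or not it was seen in that year.
Records the data do not cover carry latent covariates (normal imputation
layer) and latent reproduction (the fecundity chain itself); survival over
the interval following year t is logit-linear in the year-t covariates and
standardized reproduction totals, and enters the likelihood through the
forward-recursion mark-recapture-recovery kernel, which marginalizes the
latent alive/dead state.  Because every likelihood term (fecundity record,
encounter history, imputation cell) belongs to exactly one individual,
latent proposals are accepted or rejected per individual, making each
update a valid Metropolis step.

For speed the sampler caches the four linear predictors per record and the
per-individual history log-likelihoods, and updates them incrementally: a
single-column latent proposal shifts a cached predictor by ``b * dx``
instead of rebuilding the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from owlpath import imputation as imp
from owlpath.covariate_prep import standardize
from owlpath.exceptions import ConstantCovariateError, DataError, InitializationError
from owlpath.params import (
    SEXES,
    EggModelCoefficients,
    FledgeModelCoefficients,
    HatchModelCoefficients,
    ModelParameters,
    SurvivalCoefficients,
)
from owlpath.survival_mrr import mrr_loglik_matrix
from owlpath.synthetic_data import ANNUAL_COVARIATES

_SUBMODELS = {
    "egg": EggModelCoefficients,
    "hatch": HatchModelCoefficients,
    "fledge": FledgeModelCoefficients,
    "survival": SurvivalCoefficients,
}
_GAMMALN = special.gammaln
_FEC = ("egg", "hatch", "fledge")

# log(x!) lookup for the small integer counts of the reproduction chain
_LOGFACT_TABLE = special.gammaln(np.arange(2048) + 1.0)


def _logfact(x):
    """log(x!) for integer-valued arrays (NaN when negative)."""
    xi = np.asarray(x)
    idx = np.clip(xi, 0, _LOGFACT_TABLE.size - 1).astype(np.intp)
    out = _LOGFACT_TABLE[idx]
    if np.any(xi < 0):
        out = np.where(xi < 0, np.nan, out)
    if np.any(xi >= _LOGFACT_TABLE.size - 1):
        out = np.where(
            xi >= _LOGFACT_TABLE.size - 1, _GAMMALN(np.asarray(x, dtype=float) + 1.0), out
        )
    return out


def _log1pexp(x):
    return np.logaddexp(0.0, x)


@dataclass
class _State:
    """Mutable per-chain sampler state (leading axis = chains)."""

    beta: dict  # (submodel, sex) -> (C, P)
    det_logit: np.ndarray  # (C, 4): p_ring, p_vhf, r_ring, r_vhf
    zval: dict  # covariate column -> (C, R)
    spot: np.ndarray  # (C, n_ind)
    E: np.ndarray  # (C, R) float counts
    N: np.ndarray
    F: np.ndarray
    hyper_mu: dict  # column -> (C, G)
    hyper_logsd: dict  # column -> (C, G)
    eta: dict = None  # submodel -> cached linear predictor (C, R)
    phi_mat: np.ndarray = None  # (C, n_ind, n_years)
    mrr_ll: np.ndarray = None  # (C, n_ind)


class JointModel:
    """Joint fecundity / MRR / imputation model over one dataset."""

    @classmethod
    def from_dataset(cls, dataset, spec: imp.ImputationSpec | None = None, **kwargs):
        """Build the model from a :class:`SimulatedDataset`-like object."""
        return cls(dataset.individuals, dataset.annual, dataset.encounters, spec=spec, **kwargs)

    def __init__(
        self,
        individuals,
        annual,
        encounters,
        spec: imp.ImputationSpec | None = None,
        prior_scale: float = 1.5,
        latent_every: int = 2,
        scalers: dict | None = None,
    ):
        self.spec = spec if spec is not None else imp.ImputationSpec()
        self.spec.validate()
        self.prior_scale = float(prior_scale)
        # Latent covariate cells and imputation hyperparameters are refreshed
        # every `latent_every`-th sweep (partial updating; the coefficient,
        # detection and latent-reproduction blocks run every sweep).
        self.latent_every = max(int(latent_every), 1)

        self.individuals = individuals.reset_index(drop=True)
        occ_cols = sorted(
            (c for c in encounters.columns if c.startswith("occ_")),
            key=lambda c: int(c.split("_")[1]),
        )
        enc = encounters.set_index("id").loc[self.individuals["id"]]
        self.codes = enc[occ_cols].to_numpy(dtype=int)
        self.n_ind, self.n_occ = self.codes.shape
        self.n_years = self.n_occ - 1
        self.first = self.individuals["first_occasion"].to_numpy(dtype=int)
        self.sex_ind = self.individuals["sex"].to_numpy()
        self.group_ind = self.individuals["tag_group"].to_numpy()
        self.vhf = self.group_ind == "vhf"
        self.fem_ind = self.sex_ind == "F"

        # Record grid: one row per individual-year from first capture up to
        # the last year the bird could have been alive (a dead recovery at
        # occasion k proves death in interval k-1, so years >= k are
        # dropped: their latent values would only ever see their prior).
        id_to_row = {int(v): i for i, v in enumerate(self.individuals["id"])}
        last_year = np.full(self.n_ind, self.n_years - 1, dtype=int)
        for i in range(self.n_ind):
            rec = np.flatnonzero(self.codes[i] == 2)
            if rec.size:
                last_year[i] = rec[0] - 1
        rec_id, rec_year = [], []
        for i in range(self.n_ind):
            for y in range(self.first[i], last_year[i] + 1):
                rec_id.append(i)
                rec_year.append(y)
        self.rec_id = np.asarray(rec_id, dtype=int)
        self.rec_year = np.asarray(rec_year, dtype=int)
        self.R = self.rec_id.size
        self.fem_rec = self.fem_ind[self.rec_id]
        self.exp_rec = (self.rec_year > self.first[self.rec_id]).astype(float)
        self.sel_sex = {
            "F": np.flatnonzero(self.fem_rec),
            "M": np.flatnonzero(~self.fem_rec),
        }
        self.ind_sex = {
            "F": np.flatnonzero(self.fem_ind),
            "M": np.flatnonzero(~self.fem_ind),
        }
        # local index (within the sex's individual subset) of each sex record
        self._local_ind = {
            s: np.searchsorted(self.ind_sex[s], self.rec_id[self.sel_sex[s]])
            for s in SEXES
        }

        # Merge observed annual data onto the grid.
        slot = {}
        for pos, (i, y) in enumerate(zip(self.rec_id, self.rec_year)):
            slot[(i, y)] = pos
        obs_cols = {c: np.full(self.R, np.nan) for c in ANNUAL_COVARIATES}
        obs_E = np.full(self.R, np.nan)
        obs_N = np.full(self.R, np.nan)
        obs_F = np.full(self.R, np.nan)
        for _, row in annual.iterrows():
            key = (id_to_row[int(row["id"])], int(row["occasion"]))
            if key not in slot:
                raise DataError(f"annual row {key} outside the individual's occasion range")
            pos = slot[key]
            for c in ANNUAL_COVARIATES:
                if c in annual.columns:
                    obs_cols[c][pos] = row[c]
            obs_E[pos] = row.get("eggs", np.nan)
            obs_N[pos] = row.get("nestlings", np.nan)
            obs_F[pos] = row.get("fledglings", np.nan)

        # Standardize each covariate over its observed cells.
        self.zobs: dict[str, np.ndarray] = {}
        self.scalers: dict[str, tuple[float, float]] = {}
        self.mis_rec: dict[str, np.ndarray] = {}
        fixed = scalers or {}
        for c in ANNUAL_COVARIATES:
            x = obs_cols[c]
            if c in fixed:
                mean, sd = fixed[c]
                z = (x - mean) / sd
            else:
                try:
                    z, mean, sd = standardize(x)
                except ConstantCovariateError:
                    z, mean, sd = x.copy(), 0.0, 1.0
            self.zobs[c] = z
            self.scalers[c] = (mean, sd)
            self.mis_rec[c] = np.flatnonzero(np.isnan(z))

        spot_raw = self.individuals["spot_diameter_mm"].to_numpy(dtype=float)
        if "spot" in fixed:
            sm, ss = fixed["spot"]
            spot_z = (spot_raw - sm) / ss
        else:
            try:
                spot_z, sm, ss = standardize(spot_raw)
            except ConstantCovariateError:
                spot_z, sm, ss = spot_raw.copy(), 0.0, 1.0
        self.spot_obs = spot_z
        self.scalers["spot"] = (sm, ss)
        self.mis_spot = np.flatnonzero(np.isnan(spot_z))

        self.obs_E, self.obs_N, self.obs_F = obs_E, obs_N, obs_F
        self.misE = np.isnan(obs_E)
        self.misN = np.isnan(obs_N)
        self.misF = np.isnan(obs_F)
        self.mis_repro = np.flatnonzero(self.misE | self.misN | self.misF)

        def _count_scaler(x):
            v = x[~np.isnan(x)]
            if v.size < 2 or v.std(ddof=1) == 0:
                return (float(v.mean()) if v.size else 6.0, 1.0)
            return float(v.mean()), float(v.std(ddof=1))

        self.scale_E = fixed.get("eggs", _count_scaler(obs_E))
        self.scale_N = fixed.get("nestlings", _count_scaler(obs_N))
        self.scale_F = fixed.get("fledglings", _count_scaler(obs_F))

        # Imputation group indices per covariate column (grid-level frame).
        grid = pd.DataFrame(
            {"id": self.individuals["id"].to_numpy()[self.rec_id], "occasion": self.rec_year}
        )
        self.gidx: dict[str, np.ndarray] = {}
        self.n_groups: dict[str, int] = {}
        for c in ANNUAL_COVARIATES:
            labels = imp.group_labels(self.spec.grouping(c), grid, self.individuals)
            uniq, gi = np.unique(labels, return_inverse=True)
            self.gidx[c] = gi
            self.n_groups[c] = uniq.size

        self.latent_cols = [c for c in ANNUAL_COVARIATES if self.mis_rec[c].size > 0]
        self.col_models: dict[str, list[str]] = {
            c: [w for w, cls in _SUBMODELS.items() if c in cls.TERMS]
            for c in ANNUAL_COVARIATES
        }

        # Static index structures for the latent updates.  Records are laid
        # out sorted by individual, so per-individual sums over latent cells
        # are contiguous segments (np.add.reduceat).
        def _per_ind(mis):
            mis_ind = self.rec_id[mis]
            aff, starts = np.unique(mis_ind, return_index=True)
            return {
                "mis": mis,
                "mis_ind": mis_ind,
                "aff": aff,
                "starts": starts,
                "local": np.searchsorted(aff, mis_ind),
            }

        self._latent_static = {}
        for c in self.latent_cols:
            st = _per_ind(self.mis_rec[c])
            st["gi"] = self.gidx[c][self.mis_rec[c]]
            self._latent_static[c] = st
        self._repro_static = _per_ind(self.mis_repro)
        if self.mis_spot.size:
            rec_aff = np.flatnonzero(np.isin(self.rec_id, self.mis_spot))
            self._spot_static = {
                "rec_aff": rec_aff,
                "local": np.searchsorted(self.mis_spot, self.rec_id[rec_aff]),
            }

        # Sufficient statistics of the observed cells per imputation group,
        # plus a group-sorted ordering of the latent cells (for reduceat).
        self._hyper_static: dict[str, dict] = {}
        for c in self.latent_cols:
            gi, z = self.gidx[c], self.zobs[c]
            obs = ~np.isnan(z)
            G = self.n_groups[c]
            go, zo = gi[obs], z[obs]
            gm = gi[self.mis_rec[c]]
            order = np.argsort(gm, kind="stable")
            ggrp, gstart = np.unique(gm[order], return_index=True)
            self._hyper_static[c] = {
                "n_obs": np.bincount(go, minlength=G).astype(float),
                "S1_obs": np.bincount(go, weights=zo, minlength=G),
                "S2_obs": np.bincount(go, weights=zo**2, minlength=G),
                "order": order,
                "ggrp": ggrp,
                "gstart": gstart,
                "G": G,
            }
        if self.mis_spot.size:
            obs = ~np.isnan(self.spot_obs)
            zo = self.spot_obs[obs]
            self._hyper_static["spot"] = {
                "n_obs": np.array([float(obs.sum())]),
                "S1_obs": np.array([zo.sum()]),
                "S2_obs": np.array([(zo**2).sum()]),
                "order": np.arange(self.mis_spot.size),
                "ggrp": np.array([0]),
                "gstart": np.array([0]),
                "G": 1,
            }

        self.block_names = [(w, s) for w in _SUBMODELS for s in SEXES]
        self.chain_names = [
            f"{w}_{s}.{f}" for (w, s) in self.block_names
            for f in ("intercept",) + tuple("b_" + t for t in _SUBMODELS[w].TERMS[1:])
        ] + ["det.p_ring", "det.p_vhf", "det.r_ring", "det.r_vhf"]

    # -- covariate/term plumbing -------------------------------------------

    def _zcount(self, which: str, arr: np.ndarray) -> np.ndarray:
        mean, sd = {"E": self.scale_E, "N": self.scale_N, "F": self.scale_F}[which]
        return (arr - mean) / sd

    def _term(self, term: str, sel: np.ndarray, state: _State):
        if term == "experience":
            return self.exp_rec[sel]
        if term == "eggs":
            return self._zcount("E", state.E[:, sel])
        if term == "nestlings":
            return self._zcount("N", state.N[:, sel])
        if term == "fledglings":
            return self._zcount("F", state.F[:, sel])
        if term == "spot":
            return state.spot[:, self.rec_id[sel]]
        return state.zval[term][:, sel]

    def _eta(self, which: str, sel: np.ndarray, state: _State, beta_override=None):
        """Linear predictor over the selected records (full rebuild)."""
        terms = _SUBMODELS[which].TERMS
        C = state.det_logit.shape[0]
        m = sel.size
        xs = [self._term(t, sel, state) for t in terms[1:]]
        fem = self.fem_rec[sel]
        eta = np.empty((C, m))
        for sex, is_f in (("F", True), ("M", False)):
            pos = np.flatnonzero(fem == is_f)
            if pos.size == 0:
                continue
            b = state.beta[(which, sex)]
            if beta_override is not None and sex in beta_override:
                b = beta_override[sex]
            if pos.size == m:  # single-sex selection: no slicing needed
                acc = np.repeat(b[:, 0:1], m, axis=1)
                for j, x in enumerate(xs):
                    acc += b[:, j + 1 : j + 2] * x
                return acc
            acc = np.repeat(b[:, 0:1], pos.size, axis=1)
            for j, x in enumerate(xs):
                xv = x[pos] if x.ndim == 1 else x[:, pos]
                acc += b[:, j + 1 : j + 2] * xv
            eta[:, pos] = acc
        return eta

    def _slope(self, which: str, term: str, sel: np.ndarray, state: _State):
        """Per-record slope of `term` in submodel `which` (sex-resolved), (C, m)."""
        j = _SUBMODELS[which].TERMS.index(term)
        bf = state.beta[(which, "F")][:, j : j + 1]
        bm = state.beta[(which, "M")][:, j : j + 1]
        return np.where(self.fem_rec[sel][None, :], bf, bm)

    # log-likelihood kernels given the linear predictor ----------------------

    @staticmethod
    def _pois_ll(eta, E):
        return E * eta - np.exp(eta) - _logfact(E)

    @staticmethod
    def _binom_ll(eta, succ, tri):
        with np.errstate(invalid="ignore"):
            return (
                _logfact(tri)
                - _logfact(succ)
                - _logfact(tri - succ)
                + succ * eta
                - tri * _log1pexp(eta)
            )

    def _fec_ll(self, which, eta, state, sel):
        if which == "egg":
            return self._pois_ll(eta, state.E[:, sel])
        if which == "hatch":
            return self._binom_ll(eta, state.N[:, sel], state.E[:, sel])
        return self._binom_ll(eta, state.F[:, sel], state.N[:, sel])

    def _detection_ind(self, det_logit):
        p = np.where(self.vhf[None, :], special.expit(det_logit[:, 1:2]),
                     special.expit(det_logit[:, 0:1]))
        r = np.where(self.vhf[None, :], special.expit(det_logit[:, 3:4]),
                     special.expit(det_logit[:, 2:3]))
        return p, r

    def _mrr_ind(self, ind_idx, phi_sub, state):
        p, r = self._detection_ind(state.det_logit)
        return mrr_loglik_matrix(
            self.codes[ind_idx], self.first[ind_idx], phi_sub,
            p[:, ind_idx], r[:, ind_idx],
        )

    # -- initialization -----------------------------------------------------

    def _init_state(self, n_chains: int) -> _State:
        C = n_chains
        beta = {
            (w, s): np.zeros((C, len(_SUBMODELS[w].TERMS))) for w in _SUBMODELS for s in SEXES
        }
        det_logit = np.tile(
            np.array([0.0, 0.0, special.logit(0.2), special.logit(0.2)]), (C, 1)
        )
        zval = {}
        hyper_mu, hyper_logsd = {}, {}
        for c in ANNUAL_COVARIATES:
            z = np.tile(self.zobs[c], (C, 1))
            if self.mis_rec[c].size:
                mom = imp.impute_covariate(self.zobs[c], self.spec, self.gidx[c])
                z[:, self.mis_rec[c]] = mom.cell_mean[None, :]
                G = self.n_groups[c]
                mu = np.array([mom.group_mean.get(g, 0.0) for g in range(G)])
                sd = np.array([max(mom.group_sd.get(g, 1.0), 1e-3) for g in range(G)])
                hyper_mu[c] = np.tile(mu, (C, 1))
                hyper_logsd[c] = np.tile(np.log(sd), (C, 1))
            zval[c] = z
        spot = np.tile(self.spot_obs, (C, 1))
        if self.mis_spot.size:
            obs = self.spot_obs[~np.isnan(self.spot_obs)]
            fill = float(obs.mean()) if obs.size else 0.0
            spot[:, self.mis_spot] = fill
            hyper_mu["spot"] = np.full((C, 1), fill)
            hyper_logsd["spot"] = np.zeros((C, 1))

        typical = self.scale_E[0] if np.isfinite(self.scale_E[0]) else 6.0
        E0, N0, F0 = imp.latent_reproduction_init(
            self.obs_E, self.obs_N, self.obs_F, typical_eggs=max(typical, 1.0)
        )
        state = _State(
            beta=beta,
            det_logit=det_logit,
            zval=zval,
            spot=spot,
            E=np.tile(E0.astype(float), (C, 1)),
            N=np.tile(N0.astype(float), (C, 1)),
            F=np.tile(F0.astype(float), (C, 1)),
            hyper_mu=hyper_mu,
            hyper_logsd=hyper_logsd,
        )
        self._refresh_caches(state)
        return state

    def _refresh_caches(self, state: _State) -> None:
        allrec = np.arange(self.R)
        C = state.det_logit.shape[0]
        state.eta = {w: self._eta(w, allrec, state) for w in _SUBMODELS}
        state.phi_mat = np.full((C, self.n_ind, self.n_years), 0.5)
        state.phi_mat[:, self.rec_id, self.rec_year] = special.expit(state.eta["survival"])
        state.mrr_ll = self._mrr_ind(np.arange(self.n_ind), state.phi_mat, state)

    def _total_fec_ll(self, state):
        allrec = np.arange(self.R)
        return (
            self._fec_ll("egg", state.eta["egg"], state, allrec)
            + self._fec_ll("hatch", state.eta["hatch"], state, allrec)
            + self._fec_ll("fledge", state.eta["fledge"], state, allrec)
        )

    # -- full log posterior (contract surface) ------------------------------

    def log_posterior(self, params: ModelParameters, hypers: dict | None = None) -> float:
        """Total log posterior at the given parameters.

        Sums the egg, hatch and fledge log-likelihoods (per sex), the MRR
        history log-likelihoods, the coefficient log-priors and, when
        ``hypers`` maps covariate columns to (mu, sd) group arrays, the
        imputation-layer log-densities and their hyperpriors.  Requires
        complete data (use :meth:`fit` when latent quantities exist).
        """
        params.validate()
        if hypers is None and self.R > 0:
            if any(self.mis_rec[c].size for c in self.latent_cols):
                raise DataError(
                    "dataset has missing covariates; evaluate through fit() or supply hypers"
                )
            if self.mis_repro.size:
                raise DataError("dataset has unobserved reproduction; evaluate through fit()")
        lp = 0.0
        ps = self.prior_scale
        for w, s, coeffs in params.submodels():
            lp += float(-0.5 * (coeffs.as_array() ** 2).sum() / ps**2)
        state = self._params_state(params)
        if self.R > 0:
            lp += float(self._total_fec_ll(state).sum())
        lp += float(state.mrr_ll.sum())
        if hypers is not None:
            for c, (mu, sd) in hypers.items():
                x = self.zobs[c] if c != "spot" else self.spot_obs
                gi = self.gidx[c] if c != "spot" else np.zeros(x.size, dtype=int)
                obs = ~np.isnan(x)
                lp += float(
                    np.sum(
                        -np.log(sd[gi[obs]])
                        - 0.5 * ((x[obs] - mu[gi[obs]]) / sd[gi[obs]]) ** 2
                    )
                )
                lp += float(
                    np.sum(-0.5 * (mu / self.spec.mean_prior_scale) ** 2)
                    + np.sum(-0.5 * (sd / self.spec.sd_prior_scale) ** 2)
                )
        return lp

    def _params_state(self, params: ModelParameters) -> _State:
        state = self._init_state(1)
        for (w, s) in self.block_names:
            state.beta[(w, s)] = getattr(params, w)[s].as_array()[None, :]
        det = params.detection
        state.det_logit = special.logit(
            np.array([[det.p_ring, det.p_vhf, det.r_ring, det.r_vhf]])
        )
        if self.R > 0 and not self.mis_repro.size:
            state.E = self.obs_E[None, :].copy()
            state.N = self.obs_N[None, :].copy()
            state.F = self.obs_F[None, :].copy()
        self._refresh_caches(state)
        return state

    # -- initialization at the posterior mode --------------------------------

    def _map_initialize(self, state: _State):
        """Start every block at a mode estimate with curvature-based proposals.

        Fecundity blocks: complete-case maximum likelihood (IRLS-style BFGS)
        with the inverse Fisher information as initial proposal covariance.
        Survival and detection: BFGS on the MRR log-likelihood evaluated at
        the mean-imputed latent initialization.  Removes the burn-in
        transient so the covariance adaptation learns the posterior, not
        the approach to it.
        """
        from scipy import optimize

        from owlpath.fecundity import fit_binomial_mle, fit_poisson_mle

        C = state.det_logit.shape[0]
        proposals: dict = {}

        def _complete_design(which, sel):
            terms = _SUBMODELS[which].TERMS[1:]
            cols, ok = [], np.ones(sel.size, dtype=bool)
            for t in terms:
                if t == "experience":
                    x = self.exp_rec[sel]
                elif t == "eggs":
                    x = self._zcount("E", self.obs_E[sel])
                elif t == "nestlings":
                    x = self._zcount("N", self.obs_N[sel])
                elif t == "fledglings":
                    x = self._zcount("F", self.obs_F[sel])
                elif t == "spot":
                    x = self.spot_obs[self.rec_id[sel]]
                else:
                    x = self.zobs[t][sel]
                ok &= ~np.isnan(x)
                cols.append(x)
            X = np.column_stack([np.ones(sel.size)] + cols)
            return X, ok

        for sex in SEXES:
            sel = self.sel_sex[sex]
            for which, resp, tri in (
                ("egg", self.obs_E, None),
                ("hatch", self.obs_N, self.obs_E),
                ("fledge", self.obs_F, self.obs_N),
            ):
                X, ok = _complete_design(which, sel)
                y = resp[sel]
                ok &= ~np.isnan(y)
                if tri is not None:
                    n_tr = tri[sel]
                    ok &= ~np.isnan(n_tr)
                if ok.sum() < 10 * X.shape[1]:
                    continue
                try:
                    if tri is None:
                        beta, se = fit_poisson_mle(X[ok], y[ok])
                    else:
                        beta, se = fit_binomial_mle(X[ok], y[ok], n_tr[ok])
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.all(np.isfinite(beta)) and np.all(np.isfinite(se)):
                    state.beta[(which, sex)][:] = np.clip(beta, -10, 10)
                    proposals[(which, sex)] = np.diag(np.minimum(se, 1.0))

        # survival + detection: BFGS on the marginal MRR log-likelihood at
        # the latent initialization (one chain's state)
        allrec = np.arange(self.R)
        Z = np.empty((self.R, len(SurvivalCoefficients.TERMS)))
        Z[:, 0] = 1.0
        for j, t in enumerate(SurvivalCoefficients.TERMS[1:], start=1):
            v = self._term(t, allrec, state)
            Z[:, j] = v[0] if np.ndim(v) == 2 else v
        P = Z.shape[1]
        fem = self.fem_rec

        def negll(x):
            beta_f, beta_m = x[:P], x[P : 2 * P]
            eta = np.where(fem, Z @ beta_f, Z @ beta_m)
            phi = np.zeros((1, self.n_ind, self.n_years))
            phi[0, self.rec_id, self.rec_year] = special.expit(eta)
            dl = x[2 * P :][None, :]
            p = np.where(self.vhf, special.expit(dl[:, 1:2]), special.expit(dl[:, 0:1]))
            r = np.where(self.vhf, special.expit(dl[:, 3:4]), special.expit(dl[:, 2:3]))
            ll = mrr_loglik_matrix(self.codes, self.first, phi, p, r).sum()
            prior = -0.5 * (x[: 2 * P] ** 2).sum() / self.prior_scale**2
            return -(ll + prior)

        x0 = np.concatenate([np.zeros(2 * P), state.det_logit[0]])
        try:
            res = optimize.minimize(negll, x0, method="L-BFGS-B", options={"maxiter": 60})
            if np.all(np.isfinite(res.x)):
                state.beta[("survival", "F")][:] = np.clip(res.x[:P], -10, 10)
                state.beta[("survival", "M")][:] = np.clip(res.x[P : 2 * P], -10, 10)
                state.det_logit[:] = np.clip(res.x[2 * P :], -8, 8)
        except (ValueError, np.linalg.LinAlgError):
            pass
        return proposals

    # -- MCMC ----------------------------------------------------------------

    def fit(self, config) -> "InferenceResult":
        """Run the Metropolis-within-Gibbs sampler; see the module docstring.

        Returns an :class:`owlpath.inference.InferenceResult` whose recorded
        parameters are the 62 submodel coefficients and the four detection
        probabilities; imputation hyperparameters and latent values are
        sampled but not recorded.
        """
        from owlpath.inference import InferenceResult

        config.validate()
        if self.R == 0:
            raise DataError("cannot fit a model to an empty dataset")
        C = config.n_chains
        ss = np.random.SeedSequence(config.seed)
        rng_init, rng_coeff, rng_latent, rng_hyper = [
            np.random.default_rng(s) for s in ss.spawn(4)
        ]
        state = self._init_state(C)
        proposals = self._map_initialize(state)
        # overdisperse chain starting points slightly (coefficients only)
        for key in state.beta:
            state.beta[key] += 0.05 * rng_init.standard_normal(state.beta[key].shape)
        self._refresh_caches(state)
        if not (
            np.all(np.isfinite(self._total_fec_ll(state)))
            and np.all(np.isfinite(state.mrr_ll))
        ):
            raise InitializationError("joint posterior not finite at initial values")

        ad = {}
        for key in self.block_names:
            P = state.beta[key].shape[1]
            if key in proposals:
                ad[key] = {"scale": 2.38 / np.sqrt(P), "L": proposals[key], "buf": []}
            else:
                ad[key] = {"scale": 0.4 / np.sqrt(P), "L": np.eye(P), "buf": []}
        ad["det"] = {"scale": 0.2, "L": np.eye(4), "buf": []}
        step_col = {c: 0.5 for c in self.latent_cols}
        step_spot = 0.5
        step_hyper = {c: 0.2 for c in state.hyper_mu}

        out = np.empty((C, config.n_retained, len(self.chain_names)))
        k = 0
        for t in range(config.n_iterations):
            adapt = t < config.n_burnin
            gamma = min(0.1, 5.0 / (t + 10.0) ** 0.7) if adapt else 0.0

            for key in self.block_names:
                self._update_coeff_block(key, state, ad[key], rng_coeff, gamma, t, adapt)
            self._update_detection(state, ad["det"], rng_coeff, gamma, t, adapt)
            if t % self.latent_every == 0:
                for c in list(state.hyper_mu):
                    step_hyper[c] = self._update_hyper(c, state, step_hyper[c], rng_hyper, gamma)
                for c in self.latent_cols:
                    step_col[c] = self._update_latent_column(
                        c, state, step_col[c], rng_latent, gamma
                    )
                if self.mis_spot.size:
                    step_spot = self._update_latent_spot(state, step_spot, rng_latent, gamma)
            if self.mis_repro.size:
                self._update_latent_repro(state, rng_latent)

            if not adapt and (t - config.n_burnin) % config.thin == 0:
                vec = [state.beta[key] for key in self.block_names]
                vec.append(special.expit(state.det_logit))
                out[:, k, :] = np.concatenate(vec, axis=1)
                k += 1
        return InferenceResult(chains=out, names=list(self.chain_names), config=config)

    # individual block updates ------------------------------------------------

    def _update_coeff_block(self, key, state, ad, rng, gamma, t, adapt):
        which, sex = key
        beta = state.beta[key]
        C, P = beta.shape
        prop = beta + ad["scale"] * rng.standard_normal((C, P)) @ ad["L"].T
        dprior = (-0.5 * (prop**2).sum(-1) + 0.5 * (beta**2).sum(-1)) / self.prior_scale**2
        sel = self.sel_sex[sex]
        eta_prop = self._eta(which, sel, state, beta_override={sex: prop})
        if which in _FEC:
            eta_cur = state.eta[which][:, sel]
            delta = self._d_fec(which, eta_cur, eta_prop, state, sel).sum(-1) + dprior
            acc = np.log(rng.random(C)) < delta
            if acc.any():
                ai = np.flatnonzero(acc)
                beta[ai] = prop[ai]
                cache = state.eta[which]
                cache[np.ix_(ai, sel)] = eta_prop[ai]
        else:  # survival
            inds = self.ind_sex[sex]
            phi_prop = special.expit(eta_prop)
            phi_sub = state.phi_mat[:, inds, :].copy()
            local = self._local_ind[sex]
            phi_sub[:, local, self.rec_year[sel]] = phi_prop
            ll_prop = self._mrr_ind(inds, phi_sub, state)
            delta = ll_prop.sum(-1) - state.mrr_ll[:, inds].sum(-1) + dprior
            acc = np.log(rng.random(C)) < delta
            if acc.any():
                ai = np.flatnonzero(acc)
                beta[ai] = prop[ai]
                state.eta["survival"][np.ix_(ai, sel)] = eta_prop[ai]
                state.phi_mat[np.ix_(ai, inds)] = phi_sub[ai]
                state.mrr_ll[np.ix_(ai, inds)] = ll_prop[ai]
        if adapt:
            ad["scale"] *= np.exp(gamma * (acc.mean() - 0.234))
            ad["buf"].append(state.beta[key].copy())
            if len(ad["buf"]) > 800:
                ad["buf"].pop(0)
            if t >= 400 and t % 250 == 0:
                pooled = np.concatenate(ad["buf"], axis=0)
                cov = np.cov(pooled.T) + 1e-8 * np.eye(P)
                ad["L"] = np.linalg.cholesky(cov)
                ad["scale"] = 2.38 / np.sqrt(P)

    def _update_detection(self, state, ad, rng, gamma, t, adapt):
        C = state.det_logit.shape[0]
        cur = state.det_logit
        prop = cur + ad["scale"] * rng.standard_normal((C, 4)) @ ad["L"].T

        def prior(x):  # Uniform(0,1) prior expressed on the logit scale
            return (x - 2.0 * np.logaddexp(0.0, x)).sum(-1)

        state.det_logit = prop
        ll_prop = self._mrr_ind(np.arange(self.n_ind), state.phi_mat, state)
        state.det_logit = cur
        delta = ll_prop.sum(-1) - state.mrr_ll.sum(-1) + prior(prop) - prior(cur)
        acc = np.log(rng.random(C)) < delta
        if acc.any():
            ai = np.flatnonzero(acc)
            cur[ai] = prop[ai]
            state.mrr_ll[ai] = ll_prop[ai]
        if adapt:
            ad["scale"] *= np.exp(gamma * (acc.mean() - 0.234))
            ad["buf"].append(cur.copy())
            if len(ad["buf"]) > 800:
                ad["buf"].pop(0)
            if t >= 400 and t % 250 == 0:
                pooled = np.concatenate(ad["buf"], axis=0)
                ad["L"] = np.linalg.cholesky(np.cov(pooled.T) + 1e-8 * np.eye(4))
                ad["scale"] = 2.38 / 2.0

    def _hyper_group_ll(self, c, state, mu, logsd):
        """Imputation-layer log-density of column c's cells, summed per group.

        Combines static sufficient statistics of the observed cells with
        dynamic sums over the latent cells (contiguous after a group sort).
        """
        hs = self._hyper_static[c]
        G = hs["G"]
        if c == "spot":
            lat = state.spot[:, self.mis_spot]
        else:
            lat = state.zval[c][:, self.mis_rec[c]]
        C = lat.shape[0]
        n = np.broadcast_to(hs["n_obs"], (C, G)).copy()
        S1 = np.broadcast_to(hs["S1_obs"], (C, G)).copy()
        S2 = np.broadcast_to(hs["S2_obs"], (C, G)).copy()
        if lat.shape[1]:
            srt = lat[:, hs["order"]]
            S1_l = np.add.reduceat(srt, hs["gstart"], axis=1)
            S2_l = np.add.reduceat(srt**2, hs["gstart"], axis=1)
            cnt = np.diff(np.append(hs["gstart"], lat.shape[1]))
            n[:, hs["ggrp"]] += cnt
            S1[:, hs["ggrp"]] += S1_l
            S2[:, hs["ggrp"]] += S2_l
        var = np.exp(2.0 * logsd)
        return -n * logsd - 0.5 * (S2 - 2.0 * mu * S1 + n * mu**2) / var

    def _update_hyper(self, c, state, step, rng, gamma):
        mu, logsd = state.hyper_mu[c], state.hyper_logsd[c]
        C, G = mu.shape
        mu_p = mu + step * rng.standard_normal((C, G))
        ls_p = logsd + step * rng.standard_normal((C, G))
        ll_cur = self._hyper_group_ll(c, state, mu, logsd)
        ll_prop = self._hyper_group_ll(c, state, mu_p, ls_p)

        def hyper_prior(m, ls):
            s = np.exp(ls)
            return (
                -0.5 * (m / self.spec.mean_prior_scale) ** 2
                - 0.5 * (s / self.spec.sd_prior_scale) ** 2
                + ls  # Jacobian of the log-sd parameterization
            )

        delta = ll_prop - ll_cur + hyper_prior(mu_p, ls_p) - hyper_prior(mu, logsd)
        acc = np.log(rng.random((C, G))) < delta  # groups are disjoint
        mu[acc] = mu_p[acc]
        logsd[acc] = ls_p[acc]
        if gamma:
            step *= np.exp(gamma * (acc.mean() - 0.44))
        return step

    def _d_fec(self, which, eta_cur, eta_prop, state, sel):
        """Log-likelihood change when only the linear predictor moves."""
        if which == "egg":
            return state.E[:, sel] * (eta_prop - eta_cur) - (
                np.exp(eta_prop) - np.exp(eta_cur)
            )
        succ = state.N[:, sel] if which == "hatch" else state.F[:, sel]
        tri = state.E[:, sel] if which == "hatch" else state.N[:, sel]
        return succ * (eta_prop - eta_cur) - tri * (_log1pexp(eta_prop) - _log1pexp(eta_cur))

    def _update_latent_column(self, c, state, step, rng, gamma):
        st = self._latent_static[c]
        mis, aff, starts, local, gi = (
            st["mis"], st["aff"], st["starts"], st["local"], st["gi"],
        )
        m = mis.size
        C = state.det_logit.shape[0]
        cur = state.zval[c][:, mis]
        prop = cur + step * rng.standard_normal((C, m))
        dx = prop - cur
        mu, sd = state.hyper_mu[c], np.exp(state.hyper_logsd[c])
        d_cell = (
            -0.5 * ((prop - mu[:, gi]) / sd[:, gi]) ** 2
            + 0.5 * ((cur - mu[:, gi]) / sd[:, gi]) ** 2
        )
        eta_props = {}
        for w in self.col_models[c]:
            eta_cur = state.eta[w][:, mis]
            eta_prop = eta_cur + self._slope(w, c, mis, state) * dx
            eta_props[w] = eta_prop
            if w != "survival":
                d_cell += self._d_fec(w, eta_cur, eta_prop, state, mis)
        delta = np.add.reduceat(d_cell, starts, axis=1)  # (C, n_aff)

        phi_sub = None
        mrr_prop = None
        if "survival" in eta_props:
            phi_sub = state.phi_mat[:, aff, :].copy()
            phi_sub[:, local, self.rec_year[mis]] = special.expit(eta_props["survival"])
            mrr_prop = self._mrr_ind(aff, phi_sub, state)
            delta += mrr_prop - state.mrr_ll[:, aff]

        acc_ind = np.log(rng.random((C, aff.size))) < delta
        if acc_ind.any():
            acc_cell = acc_ind[:, local]
            cur[acc_cell] = prop[acc_cell]
            state.zval[c][:, mis] = cur
            for w, eta_prop in eta_props.items():
                cache = state.eta[w]
                tmp = cache[:, mis]
                tmp[acc_cell] = eta_prop[acc_cell]
                cache[:, mis] = tmp
            if mrr_prop is not None:
                for ci in range(C):
                    sel_ind = aff[acc_ind[ci]]
                    state.phi_mat[ci, sel_ind] = phi_sub[ci][acc_ind[ci]]
                    state.mrr_ll[ci, sel_ind] = mrr_prop[ci][acc_ind[ci]]
        if gamma:
            step *= np.exp(gamma * (acc_ind.mean() - 0.44))
        return step

    def _update_latent_spot(self, state, step, rng, gamma):
        mis = self.mis_spot
        C = state.det_logit.shape[0]
        cur = state.spot[:, mis]
        prop = cur + step * rng.standard_normal((C, mis.size))
        mu, sd = state.hyper_mu["spot"], np.exp(state.hyper_logsd["spot"])
        d_imp = -0.5 * ((prop - mu) / sd) ** 2 + 0.5 * ((cur - mu) / sd) ** 2

        rec_aff = self._spot_static["rec_aff"]
        local = self._spot_static["local"]
        # spot feeds survival only; shift the cached predictor by b_spot * dx
        dx_rec = (prop - cur)[:, local]
        eta_cur = state.eta["survival"][:, rec_aff]
        eta_prop = eta_cur + self._slope("survival", "spot", rec_aff, state) * dx_rec
        phi_sub = state.phi_mat[:, mis, :].copy()
        phi_sub[:, local, self.rec_year[rec_aff]] = special.expit(eta_prop)
        mrr_prop = self._mrr_ind(mis, phi_sub, state)
        delta = d_imp + mrr_prop - state.mrr_ll[:, mis]
        acc = np.log(rng.random((C, mis.size))) < delta
        if acc.any():
            cur[acc] = prop[acc]
            state.spot[:, mis] = cur
            acc_rec = acc[:, local]
            tmp = state.eta["survival"][:, rec_aff]
            tmp[acc_rec] = eta_prop[acc_rec]
            state.eta["survival"][:, rec_aff] = tmp
            for ci in range(C):
                sel_ind = mis[acc[ci]]
                state.phi_mat[ci, sel_ind] = phi_sub[ci][acc[ci]]
                state.mrr_ll[ci, sel_ind] = mrr_prop[ci][acc[ci]]
        if gamma:
            step *= np.exp(gamma * (acc.mean() - 0.44))
        return step

    def _update_latent_repro(self, state, rng):
        st = self._repro_static
        mis, aff, starts, local = st["mis"], st["aff"], st["starts"], st["local"]
        C = state.det_logit.shape[0]
        m = mis.size
        dE = rng.integers(-1, 2, (C, m)) * self.misE[mis]
        dN = rng.integers(-1, 2, (C, m)) * self.misN[mis]
        dF = rng.integers(-1, 2, (C, m)) * self.misF[mis]
        E, N, F = state.E[:, mis], state.N[:, mis], state.F[:, mis]
        E_p, N_p, F_p = E + dE, N + dN, F + dF
        valid = (E_p >= N_p) & (N_p >= F_p) & (F_p >= 0)

        sE, sN, sF = self.scale_E[1], self.scale_N[1], self.scale_F[1]
        eta_egg = state.eta["egg"][:, mis]
        eta_hatch = state.eta["hatch"][:, mis] + self._slope("hatch", "eggs", mis, state) * (
            dE / sE
        )
        eta_fledge = state.eta["fledge"][:, mis] + self._slope(
            "fledge", "nestlings", mis, state
        ) * (dN / sN)
        eta_surv = (
            state.eta["survival"][:, mis]
            + self._slope("survival", "nestlings", mis, state) * (dN / sN)
            + self._slope("survival", "fledglings", mis, state) * (dF / sF)
        )
        with np.errstate(invalid="ignore"):  # chain-violating proposals yield NaN
            d_rec = (
                self._pois_ll(eta_egg, E_p)
                - self._pois_ll(state.eta["egg"][:, mis], E)
                + self._binom_ll(eta_hatch, N_p, E_p)
                - self._binom_ll(state.eta["hatch"][:, mis], N, E)
                + self._binom_ll(eta_fledge, F_p, N_p)
                - self._binom_ll(state.eta["fledge"][:, mis], F, N)
            )
        d_rec = np.where(valid, d_rec, -np.inf)
        delta = np.add.reduceat(d_rec, starts, axis=1)
        phi_sub = state.phi_mat[:, aff, :].copy()
        phi_sub[:, local, self.rec_year[mis]] = special.expit(eta_surv)
        mrr_prop = self._mrr_ind(aff, phi_sub, state)
        delta += mrr_prop - state.mrr_ll[:, aff]

        acc_ind = np.log(rng.random((C, aff.size))) < delta
        if acc_ind.any():
            acc_cell = acc_ind[:, local]
            for arr, parr in ((state.E, E_p), (state.N, N_p), (state.F, F_p)):
                tmp = arr[:, mis]
                tmp[acc_cell] = parr[acc_cell]
                arr[:, mis] = tmp
            for w, eta_prop in (
                ("hatch", eta_hatch),
                ("fledge", eta_fledge),
                ("survival", eta_surv),
            ):
                cache = state.eta[w]
                tmp = cache[:, mis]
                tmp[acc_cell] = eta_prop[acc_cell]
                cache[:, mis] = tmp
            for ci in range(C):
                sel_ind = aff[acc_ind[ci]]
                state.phi_mat[ci, sel_ind] = phi_sub[ci][acc_ind[ci]]
                state.mrr_ll[ci, sel_ind] = mrr_prop[ci][acc_ind[ci]]
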