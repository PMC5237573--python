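"""BayesC and BayesD mixture-model samplers for multi-marker GWAS.

Model:  y = 1 mu + X a~ + W d~ + E,  E ~ N(0, v_e I), v_e fixed (input).

X holds mutant-allele dosages (0/1/2), W the heterozygote indicator.  Each
SNP effect theta~_j = (a~_j, d~_j) comes from a two-component mixture that
differs only by a scale factor epsilon: with prior probability pLD the SNP
is "important" (indicator gamma_j = 1) and its effect is drawn from the
large-scale distribution F, otherwise from epsilon * F.  Under F the
absolute additive effect follows a folded t distribution with df_t degrees
of freedom and scale s_a (the sign is symmetric: no frequency-dependent
sign prior is used), and the dominance effect is normal conditional on the
additive effect, d~_j | a~_j ~ N(mu_h |a~_j|, sigma_h^2 a~_j^2), which makes
|a~| and the dominance coefficient d~/|a~| independent a priori.  Because
both coordinates scale with epsilon, the conditional of d~ given a~ is the
same in both mixture components.

BayesC is the same model without the dominance term.

Sampling: the t prior is represented as a normal scale mixture with a
per-SNP latent variance psi_j ~ ScaledInv-chi2(df_t, s_a^2).  Given psi_j,
(gamma_j, a~_j) has a conjugate normal mixture full conditional in BayesC.
In BayesD, d~_j given a~_j is conjugate normal, and (gamma_j, a~_j) given
d~_j is updated by a Metropolis step that proposes from the BayesC full
conditional and accepts with the ratio of the dominance-prior densities --
a kernel whose stationary distribution is the stated posterior.

Variance components and the expected inbreeding depression enter only as
fixed inputs through the prior calibration; they are not sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.special import gammaln

__all__ = [
    "ModelInputs",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "pld_schedule",
    "calibrate_priors",
    "run_bayesc",
    "run_bayesd",
]


def pld_schedule(t: float) -> float:
    """Prior inclusion probability for the density exponent t.

    The panel size is M = 250 * 2^t SNPs per Morgan (t = 1, 2, 3, 4.8 for
    the 0.5k, 1k, 2k and 7k panels) and pLD = 5.5 * 0.7^t * 15 / M, chosen
    so that the expected number of important SNPs per QTL, pLD * M / 15 =
    5.5 * 0.7^t, approaches one as the panel approaches full sequence.
    """
    if t <= 0:
        raise ValueError("density exponent t must be positive")
    m = 250.0 * 2.0**t
    return 5.5 * 0.7**t * 15.0 / m


@dataclass
class ModelInputs:
    """Data and fixed variance inputs for a sampler run."""

    y: np.ndarray
    X: np.ndarray                 # (N, M) int dosage 0/1/2
    v_a_in: float
    v_e_in: float
    v_d_in: float = 0.0
    inb_dep_in: float = 0.0
    W: Optional[np.ndarray] = None  # heterozygote indicator; derived if None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.X = np.asarray(self.X)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be (N, M) with N = len(y)")
        if not np.isfinite(self.y).all():
            raise ValueError("phenotypes must be finite")
        bad = ~np.isin(self.X, (0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be coded 0/1/2")
        if self.W is None:
            self.W = (self.X == 1).astype(np.int8)
        else:
            self.W = np.asarray(self.W, dtype=np.int8)
            if not np.array_equal(self.W != 0, self.X == 1):
                raise ValueError("W must indicate heterozygotes of X")
        if self.v_a_in <= 0 or self.v_e_in <= 0 or self.v_d_in < 0:
            raise ValueError("variance inputs must be positive (v_d >= 0)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def freqs(self) -> np.ndarray:
        """Mutant-allele frequencies estimated from the dosage columns."""
        return self.X.mean(axis=0) / 2.0


@dataclass
class PriorSpec:
    """Calibrated prior for one sampler run."""

    pld: float
    s_a: float
    epsilon: float = 0.01
    df_t: float = 2.5
    mu_h: float = 0.0
    sigma_h: float = 0.0
    calibration_fallback: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.pld < 1.0:
            raise ValueError("pld must be in (0, 1)")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if self.df_t <= 2.0:
            raise ValueError("df_t must exceed 2 (finite prior variance)")


@dataclass
class MCMCConfig:
    n_cycles: int = 20_000
    burn_in: int = 10_000
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_cycles:
            raise ValueError("need 0 <= burn_in < n_cycles")
        if self.thin < 1 or (self.n_cycles - self.burn_in) < self.thin:
            raise ValueError("thinning leaves no stored samples")

    @property
    def n_stored(self) -> int:
        return (self.n_cycles - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned posterior draws; d_s is None for BayesC."""

    model: str
    mu_s: np.ndarray
    a_s: np.ndarray
    gamma_s: np.ndarray
    d_s: Optional[np.ndarray]
    freqs: np.ndarray
    prior: PriorSpec
    mcmc: MCMCConfig

    @property
    def n_samples(self) -> int:
        return len(self.mu_s)

    def dominance(self) -> np.ndarray:
        """Dominance-effect samples; zeros for BayesC."""
        if self.d_s is None:
            return np.zeros_like(self.a_s)
        return self.d_s

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["model"] = self.model
            for name, val in (
                ("pld", self.prior.pld), ("s_a", self.prior.s_a),
                ("epsilon", self.prior.epsilon), ("df_t", self.prior.df_t),
                ("mu_h", self.prior.mu_h), ("sigma_h", self.prior.sigma_h),
                ("n_cycles", self.mcmc.n_cycles),
                ("burn_in", self.mcmc.burn_in),
                ("thin", self.mcmc.thin), ("seed", self.mcmc.seed),
            ):
                f.attrs[name] = val
            f.create_dataset("mu", data=self.mu_s)
            f.create_dataset("a", data=self.a_s)
            f.create_dataset("gamma", data=self.gamma_s)
            f.create_dataset("freqs", data=self.freqs)
            if self.d_s is not None:
                f.create_dataset("d", data=self.d_s)

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import h5py

        with h5py.File(path, "r") as f:
            prior = PriorSpec(
                pld=float(f.attrs["pld"]), s_a=float(f.attrs["s_a"]),
                epsilon=float(f.attrs["epsilon"]),
                df_t=float(f.attrs["df_t"]),
                mu_h=float(f.attrs["mu_h"]),
                sigma_h=float(f.attrs["sigma_h"]),
            )
            mcmc = MCMCConfig(
                n_cycles=int(f.attrs["n_cycles"]),
                burn_in=int(f.attrs["burn_in"]),
                thin=int(f.attrs["thin"]), seed=int(f.attrs["seed"]),
            )
            return cls(
                model=str(f.attrs["model"]),
                mu_s=f["mu"][:], a_s=f["a"][:], gamma_s=f["gamma"][:],
                d_s=f["d"][:] if "d" in f else None,
                freqs=f["freqs"][:], prior=prior, mcmc=mcmc,
            )


def _abs_t_mean_factor(df: float) -> float:
    """E|T| for a standard t with df > 1 degrees of freedom."""
    return float(
        2.0 * math.sqrt(df) / (math.sqrt(math.pi) * (df - 1.0))
        * math.exp(gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0))
    )


def calibrate_priors(
    inputs: ModelInputs,
    pld: float,
    epsilon: float = 0.01,
    df_t: float = 2.5,
    model: str = "C",
    freqs: Optional[np.ndarray] = None,
) -> PriorSpec:
    """Moment-match the prior scales to the input variance components.

    The additive scale s_a makes the prior-expected additive variance over
    the panel, sum_j H_j E[a~_j^2] with H_j = 2 p_j q_j, equal v_a_in:

        s_a^2 = v_a_in / [ df/(df-2) * (pLD + (1-pLD) eps^2) * sum_j H_j ]

    For BayesD, (mu_h, sigma_h) are chosen so the prior-expected dominance
    variance sum_j H_j^2 E[d~_j^2] equals v_d_in and the prior-expected
    inbreeding depression sum_j H_j E[d~_j] equals inb_dep_in, using
    E[d~] = mu_h E[|a~|] and E[d~^2] = (mu_h^2 + sigma_h^2) E[a~^2].  If the
    moment system is infeasible (the depression constraint alone already
    demands more dominance second moment than v_d_in allows), the dominance
    coefficient prior falls back to (0.2, 0.3) and the spec is flagged.
    """
    model = model.upper()
    if model not in ("C", "D"):
        raise ValueError("model must be 'C' or 'D'")
    if df_t <= 2.0:
        raise ValueError("df_t must exceed 2 (finite prior variance)")
    if inputs.v_a_in <= 0:
        raise ValueError("v_a_in must be positive")
    p = inputs.freqs() if freqs is None else np.asarray(freqs, float)
    H = 2.0 * p * (1.0 - p)
    sum_h = float(H.sum())
    sum_h2 = float((H**2).sum())
    if sum_h <= 0:
        raise ValueError("panel is entirely monomorphic")
    tvar = df_t / (df_t - 2.0)
    mix2 = pld + (1.0 - pld) * epsilon**2
    s_a2 = inputs.v_a_in / (tvar * mix2 * sum_h)
    s_a = math.sqrt(s_a2)
    mu_h = sigma_h = 0.0
    fallback = False
    if model == "D":
        if inputs.v_d_in == 0.0:
            mu_h = sigma_h = 0.0
        else:
            mix1 = pld + (1.0 - pld) * epsilon
            e_abs_a = _abs_t_mean_factor(df_t) * s_a
            mu_h = inputs.inb_dep_in / (sum_h * e_abs_a * mix1)
            e_a2 = tvar * s_a2
            md2 = inputs.v_d_in / (sum_h2 * e_a2 * mix2)
            if md2 <= mu_h**2 or not math.isfinite(md2):
                mu_h, sigma_h = 0.2, 0.3
                fallback = True
            else:
                sigma_h = math.sqrt(md2 - mu_h**2)
    return PriorSpec(
        pld=pld, s_a=s_a, epsilon=epsilon, df_t=df_t,
        mu_h=mu_h, sigma_h=sigma_h, calibration_fallback=fallback,
    )


@njit(cache=False, fastmath=True)
def _gibbs_kernel(X8, W8, xm, x2c, wm, w2c, y, v_e, pld, eps, df, s_a2,
                  mu_h, sigma_h, with_dom, like_on,
                  n_cycles, burn_in, thin, seed,
                  mu_s, a_s, d_s, g_s):  # pragma: no cover - via wrappers
    """Shared Gibbs/Metropolis sweep for BayesC (with_dom=0) and BayesD.

    X8/W8 are (M, N) int8 raw design rows; the model uses column-centred
    covariates with an explicit intercept, and the centring is carried
    algebraically: the working residual z = y - X a - W d is updated with
    cheap integer-weighted axpys, while the scalar ``const`` (intercept
    plus the column-mean corrections) and the running sum of z supply the
    centred dot products exactly.  z is float32 and is refreshed in double
    precision every 1000 cycles to stop rounding drift.  x2c/w2c are the
    centred sums of squares; xm/wm the column means.  With like_on = 0 the
    data terms are switched off and the kernel samples from the prior
    (used by the prior-reproduction correctness checks).
    """
    np.random.seed(seed)
    M = X8.shape[0]
    N = X8.shape[1]
    lam = like_on / v_e
    log_prior_odds = np.log(pld / (1.0 - pld))
    eps2 = eps * eps

    a = np.zeros(M)
    d = np.zeros(M)
    gam = np.zeros(M, dtype=np.uint8)
    psi = np.empty(M)
    for j in range(M):
        psi[j] = df * s_a2 / np.random.chisquare(df)

    # z = y - X a - W d (raw, uncentred); true centred residual is
    # z - const with const = mu - sum_j xm_j a_j - sum_j wm_j d_j
    z = np.empty(N, dtype=np.float32)
    sum_z = 0.0
    for i in range(N):
        z[i] = np.float32(y[i])
        sum_z += y[i]
    mu = sum_z / N if like_on > 0.0 else 0.0
    const = mu

    acc = np.empty(N)
    store = 0
    for cyc in range(n_cycles):
        if like_on > 0.0 and cyc % 1000 == 999:
            # double-precision residual refresh
            for i in range(N):
                acc[i] = y[i]
            for j in range(M):
                aj64 = a[j]
                if aj64 != 0.0:
                    xj8 = X8[j]
                    for i in range(N):
                        acc[i] -= xj8[i] * aj64
            if with_dom == 1:
                for j in range(M):
                    dj64 = d[j]
                    if dj64 != 0.0:
                        wj8 = W8[j]
                        for i in range(N):
                            acc[i] -= wj8[i] * dj64
            sum_z = 0.0
            for i in range(N):
                z[i] = np.float32(acc[i])
                sum_z += acc[i]
        # general mean
        if like_on > 0.0:
            resid_mean = sum_z / N - const + mu
            mu_new = resid_mean + np.sqrt(v_e / N) * np.random.standard_normal()
            const += mu_new - mu
            mu = mu_new
        for j in range(M):
            xj = X8[j]
            x2j = x2c[j]
            if x2j == 0.0 and like_on > 0.0:
                # monomorphic column: no information, effect pinned at 0
                continue
            # ---- (gamma_j, a_j): BayesC full conditional, used directly
            # (BayesC) or as a Metropolis proposal (BayesD) --------------
            if like_on > 0.0:
                dot = 0.0
                for i in range(N):
                    dot += xj[i] * z[i]
                r = dot - xm[j] * sum_z + x2j * a[j]
            else:
                r = 0.0
            psij = psi[j]
            v1 = psij
            v0 = eps2 * psij
            V1 = 1.0 / (x2j * lam + 1.0 / v1)
            V0 = 1.0 / (x2j * lam + 1.0 / v0)
            m1 = V1 * r * lam
            m0 = V0 * r * lam
            l1 = 0.5 * np.log(V1 / v1) + 0.5 * m1 * m1 / V1
            l0 = 0.5 * np.log(V0 / v0) + 0.5 * m0 * m0 / V0
            zst = log_prior_odds + l1 - l0
            if zst > 35.0:
                p1 = 1.0
            elif zst < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-zst))
            g_new = 1 if np.random.random() < p1 else 0
            if g_new == 1:
                a_new = m1 + np.sqrt(V1) * np.random.standard_normal()
            else:
                a_new = m0 + np.sqrt(V0) * np.random.standard_normal()
            accept = True
            if with_dom == 1 and sigma_h > 0.0:
                # Metropolis correction by the dominance-prior ratio
                dj = d[j]
                a_old = a[j]
                if a_old == 0.0:
                    accept = True
                elif a_new == 0.0:
                    accept = False
                else:
                    sd_new = sigma_h * np.abs(a_new)
                    sd_old = sigma_h * np.abs(a_old)
                    ln_new = (-np.log(sd_new)
                              - 0.5 * ((dj - mu_h * np.abs(a_new)) / sd_new) ** 2)
                    ln_old = (-np.log(sd_old)
                              - 0.5 * ((dj - mu_h * np.abs(a_old)) / sd_old) ** 2)
                    lr = ln_new - ln_old
                    if lr >= 0.0:
                        accept = True
                    else:
                        accept = np.log(np.random.random()) < lr
            if accept:
                diff = a_new - a[j]
                if diff != 0.0 and like_on > 0.0:
                    d32 = np.float32(diff)
                    for i in range(N):
                        z[i] -= xj[i] * d32
                    sum_z -= N * xm[j] * diff
                    const -= xm[j] * diff
                a[j] = a_new
                gam[j] = g_new
            # ---- d_j | a_j: conjugate normal (BayesD only) --------------
            if with_dom == 1:
                aj = a[j]
                wj = W8[j]
                w2j = w2c[j]
                if sigma_h <= 0.0 or aj == 0.0:
                    d_new = mu_h * np.abs(aj)
                else:
                    pvar = sigma_h * sigma_h * aj * aj
                    pmean = mu_h * np.abs(aj)
                    if like_on > 0.0:
                        dotd = 0.0
                        for i in range(N):
                            dotd += wj[i] * z[i]
                        rd = dotd - wm[j] * sum_z + w2j * d[j]
                    else:
                        rd = 0.0
                    Vd = 1.0 / (w2j * lam + 1.0 / pvar)
                    md = Vd * (rd * lam + pmean / pvar)
                    d_new = md + np.sqrt(Vd) * np.random.standard_normal()
                diffd = d_new - d[j]
                if diffd != 0.0 and like_on > 0.0:
                    dd32 = np.float32(diffd)
                    for i in range(N):
                        z[i] -= wj[i] * dd32
                    sum_z -= N * wm[j] * diffd
                    const -= wm[j] * diffd
                d[j] = d_new
            # ---- latent t-scale ----------------------------------------
            c = 1.0 if gam[j] == 1 else eps2
            psi[j] = (df * s_a2 + a[j] * a[j] / c) / np.random.chisquare(df + 1.0)
        if cyc >= burn_in and (cyc - burn_in + 1) % thin == 0:
            mu_s[store] = mu
            for j in range(M):
                a_s[store, j] = a[j]
                g_s[store, j] = gam[j]
            if with_dom == 1:
                for j in range(M):
                    d_s[store, j] = d[j]
            store += 1
    return store


def _prepare(inputs: ModelInputs):
    n = inputs.n
    X8 = np.ascontiguousarray(inputs.X.T.astype(np.int8))
    xm = X8.mean(axis=1)
    x2c = (X8.astype(np.float64) ** 2).sum(axis=1) - n * xm**2
    # centred sums of squares of exactly-constant columns are tiny negative
    # or positive round-off; clamp them to zero
    x2c[np.abs(x2c) < 1e-9 * n] = 0.0
    W8 = np.ascontiguousarray(inputs.W.T.astype(np.int8))
    wm = W8.mean(axis=1)
    w2c = (W8.astype(np.float64) ** 2).sum(axis=1) - n * wm**2
    w2c[np.abs(w2c) < 1e-9 * n] = 0.0
    return X8, xm, x2c, W8, wm, w2c


def _run(inputs: ModelInputs, prior: PriorSpec, mcmc: MCMCConfig,
         with_dom: bool, likelihood: bool) -> PosteriorSamples:
    X8, xm, x2c, W8, wm, w2c = _prepare(inputs)
    n_s = mcmc.n_stored
    M = inputs.m
    mu_s = np.zeros(n_s)
    a_s = np.zeros((n_s, M))
    g_s = np.zeros((n_s, M), dtype=np.uint8)
    d_s = np.zeros((n_s, M)) if with_dom else np.zeros((1, 1))
    stored = _gibbs_kernel(
        X8, W8, xm, x2c, wm, w2c, inputs.y, inputs.v_e_in,
        prior.pld, prior.epsilon, prior.df_t, prior.s_a**2,
        prior.mu_h, prior.sigma_h,
        1 if with_dom else 0, 1.0 if likelihood else 0.0,
        mcmc.n_cycles, mcmc.burn_in, mcmc.thin,
        mcmc.seed % (2**31 - 1),
        mu_s, a_s, d_s, g_s,
    )
    assert stored == n_s
    return PosteriorSamples(
        model="bayesd" if with_dom else "bayesc",
        mu_s=mu_s, a_s=a_s, gamma_s=g_s,
        d_s=d_s if with_dom else None,
        freqs=inputs.freqs(), prior=prior, mcmc=mcmc,
    )


def run_bayesc(inputs: ModelInputs, prior: PriorSpec, mcmc: MCMCConfig,
               likelihood: bool = True) -> PosteriorSamples:
    """Additive-only mixture model.  ``likelihood=False`` switches the data
    terms off so the chain samples the prior (correctness checks)."""
    return _run(inputs, prior, mcmc, with_dom=False, likelihood=likelihood)


def run_bayesd(inputs: ModelInputs, prior: PriorSpec, mcmc: MCMCConfig,
               likelihood: bool = True) -> PosteriorSamples:
    """Additive + dominance mixture model."""
    return _run(inputs, prior, mcmc, with_dom=True, likelihood=likelihood)
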