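"""Probabilistic genotyping of sequenced mixtures from allele read counts.

Model
-----
For a mixture of ``noc`` contributors with mixture proportions ``omega``
(simplex), panel-wide expected depth ``mu`` (reads per locus at efficiency
1) and shared negative-binomial dispersion ``theta``, the expected read
count of allele *a* at locus *l* under a proposed genotype set is::

    E[a] = mu * efficiency(l) * sum_k omega_k * dose_k(a) / 2

where ``dose_k(a)`` counts allele copies in contributor *k*'s genotype.
For STR loci a calibrated fraction of each parent allele's expectation is
redistributed to its one-repeat-shorter (n-1) stutter sequence.  Observed
(retained) counts of expected alleles follow NB(mean E, dispersion theta);
an expected allele that was *not* retained contributes the probability of
falling below the analytical threshold (drop-out); retained alleles with no
expected contribution are noise, with a Poisson law on the number of noise
alleles per locus and a geometric law on their counts.

Unknown contributors are marginalised by exact enumeration of unordered
genotypes over the locus's observed alleles plus the drop-out symbol ``Q``,
weighted by Hardy-Weinberg priors from the allele frequency table (``Q``
takes the residual frequency mass).  Parameters are fitted by maximum
likelihood with a deterministic multi-start grid on the proportion simplex
followed by Nelder-Mead refinement, so identical inputs give identical
fits.  The likelihood ratio compares the fitted suspect-conditioned
hypothesis Hp against the all-unknown hypothesis Hd:
``log10 LR = (logL_hp - logL_hd) / ln 10``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .calibration import CalibrationModel
from .calling import AlleleCountTable
from .population import AlleleFrequencyTable, GenotypeProfile

#: drop-out symbol: "some allele that was not retained"
Q = "Q"

#: expected-count floor below which an allele is treated as not contributed
_EPS = 1e-9

#: cap on enumerated observed alleles per locus, by contributor count
_ALLELE_CAP = {1: 10, 2: 8, 3: 6}

LN10 = math.log(10.0)


@dataclass(frozen=True)
class Hypothesis:
    """Number of contributors and the profiles conditioned as known."""

    noc: int
    known_contributors: tuple = ()

    def __post_init__(self):
        if len(self.known_contributors) > self.noc:
            raise ValueError("more known contributors than contributors")
        if self.noc < 1:
            raise ValueError("noc must be >= 1")

    @property
    def n_unknowns(self) -> int:
        return self.noc - len(self.known_contributors)


@dataclass
class FitResult:
    """Maximum-likelihood fit of (omega, mu, theta) for one hypothesis."""

    omega: tuple               # sorted descending
    omega_by_contributor: tuple  # knowns first, then unknowns
    mu: float
    theta: float
    log_likelihood: float
    per_locus_log_likelihood: dict
    hypothesis: Hypothesis


@dataclass
class GenotypeCall:
    genotype: tuple
    posterior: float
    dropout: bool


@dataclass
class DeconvolutionResult:
    """Per-locus, per-contributor top genotypes with posteriors.

    Contributors are indexed by descending fitted proportion; ``calls`` maps
    locus -> [GenotypeCall per contributor rank].
    """

    fit: FitResult
    calls: dict
    p_threshold: float = 0.9

    def is_determinate(self, locus: str, rank: int) -> bool:
        call = self.calls[locus][rank]
        return call.posterior >= self.p_threshold and not call.dropout


@dataclass
class LRResult:
    log10_lr: float
    logl_hp: float
    logl_hd: float
    per_locus_log10_lr: dict
    fit_hp: FitResult
    fit_hd: FitResult


def enumerate_genotypes(observed_alleles, allow_dropout: bool) -> list:
    """All unordered allele pairs over the observed alleles (plus ``Q``)."""
    symbols = list(observed_alleles) + ([Q] if allow_dropout else [])
    if not symbols:
        raise ValueError("no alleles to enumerate and drop-out not allowed")
    return [
        (symbols[i], symbols[j])
        for i in range(len(symbols))
        for j in range(i, len(symbols))
    ]


def _geom_logpmf(count: int, threshold: int, p: float) -> float:
    """Geometric log-pmf for a noise count with support starting at AT."""
    k = count - threshold
    if k < 0:
        return -np.inf
    if p >= 1.0:
        return 0.0 if k == 0 else -np.inf
    return math.log(p) + k * math.log1p(-p)


def _stutter_target(allele_id: str):
    try:
        n = int(allele_id)
    except (ValueError, TypeError):
        return None
    return str(n - 1) if n >= 2 else None


class _LocusBlock:
    """Precomputed arrays for one locus under one hypothesis."""

    def __init__(self, locus, counts, hyp, calib, freqs, cap):
        self.locus = locus
        threshold = calib.analytical_threshold
        observed = dict(counts.counts.get(locus, {}))
        ordered = sorted(observed, key=lambda a: (-observed[a], a))
        kept, extra = ordered[:cap], ordered[cap:]
        # alleles beyond the enumeration cap are unconditionally noise
        self.m_extra = len(extra)
        self.g_extra = sum(
            _geom_logpmf(observed[a], threshold, calib.noise_geom_p) for a in extra
        )
        known_alleles = []
        for prof in hyp.known_contributors:
            known_alleles.extend(prof.genotypes[locus])
        universe = list(kept)
        for a in known_alleles:
            if a not in universe:
                universe.append(a)
        if calib.panel_kind == "STR":
            for a in list(universe):
                t = _stutter_target(a)
                if (
                    t is not None
                    and t not in universe
                    and calib.stutter_ratio(locus, int(a)) > 0
                ):
                    universe.append(t)
        self.alleles = universe  # without Q
        self.symbols = universe + [Q]
        A = len(self.symbols)
        self.A = A
        idx = {a: i for i, a in enumerate(self.symbols)}

        # universe ordering guarantees observed columns come first
        self.n_obs = len(kept)
        self.c = np.zeros(A)
        for a in kept:
            self.c[idx[a]] = observed[a]
        self.obs = self.c >= threshold
        assert self.obs[: self.n_obs].all() and not self.obs[self.n_obs :].any()
        self.geom = np.array(
            [
                _geom_logpmf(int(cc), threshold, calib.noise_geom_p) if o else 0.0
                for cc, o in zip(self.c, self.obs)
            ]
        )
        self.eff = calib.locus_efficiency[locus]

        # stutter redistribution matrix (shed fraction from expected ratio)
        S = np.eye(A)
        if calib.panel_kind == "STR":
            for a in universe:
                t = _stutter_target(a)
                if t is None or t not in idx:
                    continue
                ratio = calib.stutter_ratio(locus, int(a))
                shed = ratio / (1.0 + ratio)
                i = idx[a]
                S[i, i] = 1.0 - shed
                S[i, idx[t]] = shed
        self.S = S

        # known contributor dose vectors
        self.known_dose = np.zeros((len(hyp.known_contributors), A))
        for k, prof in enumerate(hyp.known_contributors):
            for a in prof.genotypes[locus]:
                self.known_dose[k, idx[a]] += 1.0

        # unknown-contributor genotypes, doses, HWE log-priors
        p = np.array([freqs.get(locus, a) for a in universe])
        p_q = max(1.0 - p.sum(), freqs.floor)
        pfull = np.concatenate([p, [p_q]])
        self.genotypes = enumerate_genotypes(universe, allow_dropout=True)
        n_g = len(self.genotypes)
        self.G = np.zeros((n_g, A))
        self.logprior_g = np.zeros(n_g)
        for g, (a, b) in enumerate(self.genotypes):
            self.G[g, idx[a]] += 1.0
            self.G[g, idx[b]] += 1.0
            pa, pb = pfull[idx[a]], pfull[idx[b]]
            self.logprior_g[g] = (
                math.log(2.0 * pa * pb) if a != b else math.log(pa * pa)
            )
        self.n_g = n_g


class MixtureModel:
    """Vectorised panel likelihood for one (counts, hypothesis) pair.

    Loci are grouped by array shape so every objective evaluation is a
    handful of tensor operations per shape bucket.
    """

    def __init__(
        self,
        counts: AlleleCountTable,
        hyp: Hypothesis,
        calib: CalibrationModel,
        freqs: AlleleFrequencyTable,
    ):
        self.counts = counts
        self.hyp = hyp
        self.calib = calib
        self.freqs = freqs
        self.threshold = calib.analytical_threshold
        cap = _ALLELE_CAP.get(hyp.noc, 6)
        self.locus_names = sorted(calib.locus_efficiency)
        blocks = [
            _LocusBlock(l, counts, hyp, calib, freqs, cap) for l in self.locus_names
        ]
        U = hyp.n_unknowns
        self._buckets = []
        by_shape: dict = {}
        for blk in blocks:
            by_shape.setdefault((blk.A, blk.n_obs), []).append(blk)
        for (A, n_obs), blks in sorted(by_shape.items()):
            n_g = blks[0].n_g
            B = len(blks)
            n_sets = n_g**U
            if U > 0:
                joint = np.array(list(iter_product(range(n_g), repeat=U)))
                joint_cols = [joint[:, u] for u in range(U)]
                idx_u = [
                    np.broadcast_to(col, (B, n_sets)) for col in joint_cols
                ]
            else:
                joint_cols = []
                idx_u = []
                n_sets = 1
            bucket = {
                "loci": [b.locus for b in blks],
                "A": A,
                "n_obs": n_obs,
                "S": n_sets,
                "c": np.stack([b.c for b in blks]),
                "geom": np.stack([b.geom for b in blks]),
                "eff": np.array([b.eff for b in blks]),
                "shed": np.stack([b.S for b in blks]),
                "known": np.stack([b.known_dose for b in blks])
                if hyp.known_contributors
                else None,
                "m_extra": np.array([b.m_extra for b in blks]),
                "g_extra": np.array([b.g_extra for b in blks]),
                "idx_u": idx_u,
                # per-unknown joint dose tensors (B, n_sets, A)
                "Du": [
                    np.stack([b.G[col] for b in blks]) for col in joint_cols
                ],
                "logprior": np.stack(
                    [
                        sum(b.logprior_g[col] for col in joint_cols)
                        if joint_cols
                        else np.zeros(1)
                        for b in blks
                    ]
                ),
                "genotypes": blks[0].genotypes,
                "blocks": blks,
            }
            self._buckets.append(bucket)

    # -- likelihood ------------------------------------------------------
    def _bucket_set_loglik(self, bucket, omega, mu, theta):
        """Log-likelihood of every genotype set: array (B, n_sets)."""
        n_known = len(self.hyp.known_contributors)
        W = 0.0
        if bucket["known"] is not None:
            known_mix = np.tensordot(
                np.asarray(omega[:n_known]), bucket["known"], axes=(0, 1)
            )  # (B, A)
            W = W + known_mix[:, None, :]
        for u, Du in enumerate(bucket["Du"]):
            W = W + omega[n_known + u] * Du
        if isinstance(W, float):  # no contributors at all cannot happen
            raise RuntimeError("empty hypothesis")
        E = 0.5 * mu * bucket["eff"][:, None, None] * np.einsum(
            "bsa,bac->bsc", W, bucket["shed"]
        )
        n_obs = bucket["n_obs"]
        r = theta
        log_r = math.log(r)
        total = bucket["logprior"].copy()

        # observed columns: NB pmf where expected, geometric noise otherwise
        if n_obs:
            Eo = E[:, :, :n_obs]
            c = bucket["c"][:, :n_obs]
            signal = Eo > _EPS
            with np.errstate(divide="ignore", invalid="ignore"):
                log_rE = np.log(r + Eo)
                logp_nb = (
                    (gammaln(c + r) - gammaln(r) - gammaln(c + 1.0))[:, None, :]
                    + r * (log_r - log_rE)
                    + c[:, None, :] * (np.log(np.maximum(Eo, _EPS)) - log_rE)
                )
            term = np.where(signal, logp_nb, bucket["geom"][:, None, :n_obs])
            total += term.sum(axis=-1)
            m = (~signal).sum(axis=-1) + bucket["m_extra"][:, None]
        else:
            m = np.broadcast_to(
                bucket["m_extra"][:, None], bucket["logprior"].shape
            ).astype(float)

        # unobserved columns: P(count < threshold) where expected, else 1
        if bucket["A"] > n_obs:
            Ed = E[:, :, n_obs:]
            signal_d = Ed > _EPS
            with np.errstate(divide="ignore", invalid="ignore"):
                log_rE = np.log(r + Ed)
                safe_logE = np.log(np.maximum(Ed, _EPS))
                acc = r * (log_r - log_rE)  # pmf at count 0
                for j in range(1, self.threshold):
                    tj = (
                        gammaln(j + r)
                        - gammaln(r)
                        - gammaln(j + 1.0)
                        + r * (log_r - log_rE)
                        + j * (safe_logE - log_rE)
                    )
                    acc = np.logaddexp(acc, tj)
            total += np.where(signal_d, acc, 0.0).sum(axis=-1)

        rate = self.calib.noise_rate
        if rate > 0:
            noise_ll = m * math.log(rate) - rate - gammaln(m + 1.0)
        else:
            noise_ll = np.where(m == 0, 0.0, -np.inf)
        return total + noise_ll + bucket["g_extra"][:, None]

    def per_locus_log_likelihood(self, omega, mu, theta) -> dict:
        out = {}
        for bucket in self._buckets:
            ll = self._bucket_set_loglik(bucket, omega, mu, theta)
            with np.errstate(divide="ignore"):
                locus_ll = logsumexp(ll, axis=1)
            for name, v in zip(bucket["loci"], locus_ll):
                out[name] = float(v)
        return out

    def log_likelihood(self, omega, mu, theta) -> float:
        return float(sum(self.per_locus_log_likelihood(omega, mu, theta).values()))

    def prune(self, omegas, mu, theta, margin: float = 60.0) -> None:
        """Drop genotype sets that are negligible at every probe point.

        For each locus, sets whose best log-likelihood over the probe
        ``omegas`` falls more than ``margin`` log units below that locus's
        best set are removed; the discarded posterior mass is below
        exp(-margin) of the total, far outside any reported precision.
        Deterministic, and a no-op on already-pruned models.
        """
        if self.hyp.n_unknowns == 0:
            return
        for bucket in self._buckets:
            if bucket["S"] <= 1:
                continue
            best = None
            for w in omegas:
                ll = self._bucket_set_loglik(bucket, np.asarray(w), mu, theta)
                best = ll if best is None else np.maximum(best, ll)
            cutoff = best.max(axis=1, keepdims=True) - margin
            keep = best >= cutoff
            K = int(keep.sum(axis=1).max())
            if K >= bucket["S"]:
                continue
            B = len(bucket["loci"])
            gather = np.zeros((B, K), dtype=int)
            valid = np.zeros((B, K), dtype=bool)
            for b in range(B):
                ks = np.flatnonzero(keep[b])
                gather[b, : len(ks)] = ks
                valid[b, : len(ks)] = True
            bucket["Du"] = [
                np.take_along_axis(Du, gather[:, :, None], axis=1)
                for Du in bucket["Du"]
            ]
            bucket["logprior"] = np.where(
                valid, np.take_along_axis(bucket["logprior"], gather, axis=1), -np.inf
            )
            bucket["idx_u"] = [
                np.take_along_axis(np.asarray(ix), gather, axis=1)
                for ix in bucket["idx_u"]
            ]
            bucket["S"] = K

    # -- posteriors ------------------------------------------------------
    def posteriors(self, omega, mu, theta) -> dict:
        """Per locus, per unknown contributor: {genotype: posterior}."""
        U = self.hyp.n_unknowns
        out: dict = {}
        for bucket in self._buckets:
            ll = self._bucket_set_loglik(bucket, omega, mu, theta)
            with np.errstate(divide="ignore"):
                norm = logsumexp(ll, axis=1, keepdims=True)
            w = np.exp(ll - norm)  # (B, n_sets)
            for bi, locus in enumerate(bucket["loci"]):
                genotypes = bucket["blocks"][bi].genotypes
                per_unknown = []
                for u in range(U):
                    ix = bucket["idx_u"][u][bi]
                    probs = np.zeros(len(genotypes))
                    np.add.at(probs, ix, w[bi])
                    per_unknown.append(
                        {g: float(p) for g, p in zip(genotypes, probs)}
                    )
                out[locus] = per_unknown
        return out


def _softmax_omega(z, noc):
    logits = np.concatenate([z, [0.0]])
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _omega_grid(noc: int):
    """Deterministic simplex starting points."""
    if noc == 1:
        return [np.array([1.0])]
    if noc == 2:
        return [np.array([w, 1.0 - w]) for w in (0.5, 0.65, 0.8, 0.9, 0.95, 0.35, 0.2, 0.1, 0.05)]
    pts = []
    steps = np.arange(1, 10)
    for i in steps:
        for j in steps:
            k = 10 - i - j
            if k >= 1:
                pts.append(np.array([i, j, k]) / 10.0)
    return pts


def fit_hypothesis(
    counts: AlleleCountTable,
    hyp: Hypothesis,
    calib: CalibrationModel,
    freqs: AlleleFrequencyTable,
    *,
    model: MixtureModel | None = None,
    n_refine: int = 2,
) -> FitResult:
    """Maximum-likelihood (omega, mu, theta) for one hypothesis.

    A fixed grid of simplex points seeds a Nelder-Mead refinement of the
    best candidates; there is no randomness in the fit.
    """
    if model is None:
        model = MixtureModel(counts, hyp, calib, freqs)
    noc = hyp.noc
    locus_totals = [counts.locus_total(l) for l in model.locus_names]
    mu0 = max(float(np.mean(locus_totals)), 1.0)
    theta0 = float(np.clip(calib.dispersion, 1.0, 1e4))

    starts = _omega_grid(noc)
    scored = []
    for w in starts:
        ll = model.log_likelihood(w, mu0, theta0)
        scored.append((ll, w))
    scored.sort(key=lambda t: -t[0])
    model.prune(starts, mu0, theta0)

    def unpack(x):
        omega = _softmax_omega(x[: noc - 1], noc)
        mu = math.exp(x[noc - 1])
        theta = math.exp(x[noc])
        return omega, mu, theta

    def objective(x):
        omega, mu, theta = unpack(x)
        if mu > 1e9 or theta > 1e8:
            return 1e12
        ll = model.log_likelihood(omega, mu, theta)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    if not np.isfinite(scored[0][0]):
        omega = np.asarray(scored[0][1])
        ll = scored[0][0]
        best = (ll, omega, mu0, theta0)
    else:
        for ll0, w in scored[:n_refine]:
            z = np.log(np.maximum(w[:-1], 1e-9)) - math.log(max(w[-1], 1e-9))
            x0 = np.concatenate([z, [math.log(mu0), math.log(theta0)]])
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={
                    "fatol": 1e-6,
                    "xatol": 1e-5,
                    "maxiter": 400 * (noc + 1),
                    "maxfev": 400 * (noc + 1),
                },
            )
            omega, mu, theta = unpack(res.x)
            ll = -res.fun
            if best is None or ll > best[0]:
                best = (ll, omega, mu, theta)

    ll, omega, mu, theta = best
    per_locus = model.per_locus_log_likelihood(omega, mu, theta)
    return FitResult(
        omega=tuple(sorted((float(w) for w in omega), reverse=True)),
        omega_by_contributor=tuple(float(w) for w in omega),
        mu=float(mu),
        theta=float(theta),
        log_likelihood=float(ll),
        per_locus_log_likelihood=per_locus,
        hypothesis=hyp,
    )


def deconvolute(
    counts: AlleleCountTable,
    noc: int,
    calib: CalibrationModel,
    freqs: AlleleFrequencyTable,
    p_threshold: float = 0.9,
) -> DeconvolutionResult:
    """Deconvolute a mixture under the all-unknown hypothesis.

    Contributor ranks are ordered by descending fitted proportion.  A call
    whose posterior is below ``p_threshold`` (strictly) or whose genotype
    proposes a drop-out is treated as Undetermined downstream.
    """
    if noc not in (1, 2, 3):
        raise ValueError("noc must be 1, 2 or 3")
    hyp = Hypothesis(noc=noc)
    model = MixtureModel(counts, hyp, calib, freqs)
    fit = fit_hypothesis(counts, hyp, calib, freqs, model=model)
    omega = np.asarray(fit.omega_by_contributor)
    rank_order = np.argsort(-omega, kind="stable")
    post = model.posteriors(omega, fit.mu, fit.theta)
    calls = {}
    for locus, per_unknown in post.items():
        per_rank = []
        for u in rank_order:
            probs = per_unknown[int(u)]
            genotype, p = max(probs.items(), key=lambda kv: (kv[1], kv[0]))
            per_rank.append(
                GenotypeCall(
                    genotype=tuple(sorted(genotype)),
                    posterior=p,
                    dropout=Q in genotype,
                )
            )
        calls[locus] = per_rank
    # re-express fit with ranked omegas
    fit = FitResult(
        omega=tuple(float(omega[i]) for i in rank_order),
        omega_by_contributor=fit.omega_by_contributor,
        mu=fit.mu,
        theta=fit.theta,
        log_likelihood=fit.log_likelihood,
        per_locus_log_likelihood=fit.per_locus_log_likelihood,
        hypothesis=hyp,
    )
    return DeconvolutionResult(fit=fit, calls=calls, p_threshold=p_threshold)


def likelihood_ratio(
    counts: AlleleCountTable,
    suspect: GenotypeProfile,
    noc: int,
    calib: CalibrationModel,
    freqs: AlleleFrequencyTable,
    *,
    fit_hd: FitResult | None = None,
) -> LRResult:
    """LR comparing "suspect + (noc-1) unknowns" against "noc unknowns".

    ``fit_hd`` may be passed to reuse the defence fit across the suspects of
    one mixture.  A numerically impossible Hp yields ``log10_lr = -inf``.
    """
    hp = Hypothesis(noc=noc, known_contributors=(suspect,))
    fit_p = fit_hypothesis(counts, hp, calib, freqs)
    if fit_hd is None:
        fit_hd = fit_hypothesis(counts, Hypothesis(noc=noc), calib, freqs)
    per_locus = {
        l: (fit_p.per_locus_log_likelihood[l] - fit_hd.per_locus_log_likelihood[l])
        / LN10
        for l in fit_p.per_locus_log_likelihood
    }
    log10_lr = (fit_p.log_likelihood - fit_hd.log_likelihood) / LN10
    return LRResult(
        log10_lr=float(log10_lr),
        logl_hp=fit_p.log_likelihood,
        logl_hd=fit_hd.log_likelihood,
        per_locus_log10_lr=per_locus,
        fit_hp=fit_p,
        fit_hd=fit_hd,
    )


def locus_log_likelihood(
    locus_counts: dict,
    genotypes,
    omega,
    mu: float,
    theta: float,
    calib: CalibrationModel,
    locus: str,
) -> float:
    """Log-likelihood of one fully specified genotype set at one locus.

    ``genotypes`` is one unordered allele pair per contributor (``Q``
    allowed); no marginalisation or priors are applied.  This is the single
    cell of the model the panel-wide engine sums over.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 1 or len(omega) != len(genotypes):
        raise ValueError("omega must match the number of genotypes")
    if abs(omega.sum() - 1.0) > 1e-9 or (omega < 0).any():
        raise ValueError("omega must lie on the simplex")
    if mu <= 0 or theta <= 0:
        raise ValueError("mu and theta must be positive")
    threshold = calib.analytical_threshold
    universe = sorted(locus_counts)
    for pair in genotypes:
        for a in pair:
            if a != Q and a not in universe:
                universe.append(a)
    if calib.panel_kind == "STR":
        for a in list(universe):
            t = _stutter_target(a)
            if t is not None and t not in universe and calib.stutter_ratio(locus, int(a)) > 0:
                universe.append(t)
    eff = calib.locus_efficiency[locus]
    dose = {a: 0.0 for a in universe}
    dose[Q] = 0.0
    for w, pair in zip(omega, genotypes):
        for a in pair:
            dose[a] = dose.get(a, 0.0) + w
    expected = {a: 0.0 for a in universe + [Q]}
    for a in universe + [Q]:
        e = 0.5 * mu * eff * dose.get(a, 0.0)
        if calib.panel_kind == "STR" and a != Q:
            t = _stutter_target(a)
            ratio = calib.stutter_ratio(locus, int(a)) if t is not None else 0.0
            if t is not None and t in expected and ratio > 0:
                shed = ratio / (1.0 + ratio)
                expected[t] += e * shed
                e *= 1.0 - shed
        expected[a] += e
    ll = 0.0
    n_noise = 0
    for a in universe:
        c = locus_counts.get(a, 0)
        e = expected[a]
        if c >= threshold and e > _EPS:
            r = theta
            ll += (
                gammaln(c + r)
                - gammaln(r)
                - gammaln(c + 1.0)
                + r * math.log(r / (r + e))
                + c * math.log(e / (r + e))
            )
        elif c >= threshold:
            n_noise += 1
            ll += _geom_logpmf(c, threshold, calib.noise_geom_p)
        elif e > _EPS:
            r = theta
            terms = [
                gammaln(j + r)
                - gammaln(r)
                - gammaln(j + 1.0)
                + r * math.log(r / (r + e))
                + (j * math.log(e / (r + e)) if j else 0.0)
                for j in range(threshold)
            ]
            ll += float(logsumexp(terms))
    if expected[Q] > _EPS:
        e, r = expected[Q], theta
        terms = [
            gammaln(j + r)
            - gammaln(r)
            - gammaln(j + 1.0)
            + r * math.log(r / (r + e))
            + (j * math.log(e / (r + e)) if j else 0.0)
            for j in range(threshold)
        ]
        ll += float(logsumexp(terms))
    rate = calib.noise_rate
    if rate > 0:
        ll += n_noise * math.log(rate) - rate - gammaln(n_noise + 1.0)
    elif n_noise > 0:
        ll = -np.inf
    return float(ll)
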