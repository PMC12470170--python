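"""Per-panel calibration from single-source samples with known genotypes.

Calibration assigns a *dose* to every called allele — 0 for noise, 1 for
each allele of a heterozygous locus, 2 for the allele of a homozygous locus
— and from the dosed counts estimates:

* ``locus_efficiency`` — each locus's mean share of a sample's assigned
  reads, normalised to mean 1 across loci;
* ``dispersion`` — a shared negative-binomial overdispersion, from the
  spread of heterozygous (dose-1) allele counts around the within-locus
  mean;
* a noise model — the expected number of above-threshold noise (dose-0)
  alleles per locus (Poisson rate) and a geometric law for their read
  counts, with support starting at the analytical threshold;
* for STR panels, a stutter model — the expected ratio of the (n-1)-repeat
  sequence's reads to its parent allele's reads, linear in the parent
  repeat number and clamped to [0, 0.5).

Stutter observations use parent alleles whose n-1 sequence is not itself a
true allele of the sample, so the stutter product is unambiguous; both
retained and below-threshold counts contribute to the measured ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .calling import AlleleCountTable
from .errors import InsufficientDataError, MissingTruthError, ModelSchemaError
from .panels import LocusPanel
from .population import GenotypeProfile

SCHEMA_VERSION = 1


@dataclass
class DoseTable:
    """Mapping (sample, locus, allele) -> dose in {0, 1, 2}."""

    doses: dict = field(default_factory=dict)

    def get(self, sample: str, locus: str, allele: str) -> int:
        return self.doses[(sample, locus, allele)]

    def items(self):
        return self.doses.items()


@dataclass
class StutterModel:
    """Expected stutter ratio (n-1 reads / parent reads) per STR locus."""

    intercept: float
    slope: float
    n_points: int

    def expected_ratio(self, repeat_number: int) -> float:
        return float(np.clip(self.intercept + self.slope * repeat_number, 0.0, 0.499))


@dataclass
class CalibrationModel:
    """Everything deconvolution needs to know about a calibrated panel."""

    panel_kind: str
    analytical_threshold: int
    locus_efficiency: dict  # locus -> positive float, mean 1
    dispersion: float
    noise_rate: float
    noise_geom_p: float
    stutter_models: dict = field(default_factory=dict)  # locus -> StutterModel
    mean_locus_reads: float = 0.0

    def validate(self) -> None:
        eff = np.array(list(self.locus_efficiency.values()))
        if len(eff) == 0 or (eff <= 0).any():
            raise ValueError("locus efficiencies must be positive")
        if abs(eff.mean() - 1.0) > 1e-6:
            raise ValueError("locus efficiencies must average to 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 < self.noise_geom_p <= 1:
            raise ValueError("noise_geom_p must be in (0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be nonnegative")
        for locus, sm in self.stutter_models.items():
            for r in (1, 10, 30):
                if not 0.0 <= sm.expected_ratio(r) < 0.5:
                    raise ValueError(f"{locus}: stutter ratio outside [0, 0.5)")

    def stutter_ratio(self, locus: str, repeat_number: int) -> float:
        sm = self.stutter_models.get(locus)
        return sm.expected_ratio(repeat_number) if sm is not None else 0.0

    # --- persistence ----------------------------------------------------
    def save(self, path) -> None:
        self.validate()
        payload = {
            "schema_version": SCHEMA_VERSION,
            "panel_kind": self.panel_kind,
            "analytical_threshold": self.analytical_threshold,
            "locus_efficiency": self.locus_efficiency,
            "dispersion": self.dispersion,
            "noise_rate": self.noise_rate,
            "noise_geom_p": self.noise_geom_p,
            "mean_locus_reads": self.mean_locus_reads,
            "stutter_models": {k: asdict(v) for k, v in self.stutter_models.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ModelSchemaError(f"cannot read calibration model: {exc}") from exc
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ModelSchemaError(
                f"unsupported schema version {payload.get('schema_version')}"
            )
        model = cls(
            panel_kind=payload["panel_kind"],
            analytical_threshold=payload["analytical_threshold"],
            locus_efficiency=payload["locus_efficiency"],
            dispersion=payload["dispersion"],
            noise_rate=payload["noise_rate"],
            noise_geom_p=payload["noise_geom_p"],
            mean_locus_reads=payload.get("mean_locus_reads", 0.0),
            stutter_models={
                k: StutterModel(**v) for k, v in payload["stutter_models"].items()
            },
        )
        model.validate()
        return model


def assign_dose(profile: GenotypeProfile, counts: AlleleCountTable) -> DoseTable:
    """Dose every retained allele of a called single-source sample."""
    table = DoseTable()
    for locus, allele_counts in counts.counts.items():
        if locus not in profile.genotypes:
            raise MissingTruthError(
                f"locus {locus} called for {counts.sample_id} but absent from truth"
            )
        a, b = profile.genotypes[locus]
        for allele in allele_counts:
            if a == b:
                dose = 2 if allele == a else 0
            else:
                dose = 1 if allele in (a, b) else 0
            table.doses[(counts.sample_id, locus, allele)] = dose
    return table


def _stutter_parent_id(allele_id: str):
    """Repeat number of the n-1 stutter product, for plain-number alleles."""
    try:
        n = int(allele_id)
    except ValueError:
        return None
    return str(n - 1) if n >= 2 else None


def _fit_geometric(counts, threshold: int) -> float:
    """MLE of the geometric parameter for counts with support >= threshold."""
    if len(counts) == 0:
        return 1.0
    excess = np.asarray(counts, dtype=float) - threshold
    return float(1.0 / (1.0 + excess.mean()))


def calibrate(samples, panel: LocusPanel) -> CalibrationModel:
    """Fit a :class:`CalibrationModel` from ``[(profile, counts), ...]``.

    Requires at least two samples of one panel.  Estimators are documented
    in the module docstring; sample order does not affect the result.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise InsufficientDataError("calibration needs at least 2 samples")
    # deterministic, order-invariant processing
    samples = sorted(samples, key=lambda pc: pc[1].sample_id)
    locus_names = panel.names
    threshold = samples[0][1].analytical_threshold

    shares = {name: [] for name in locus_names}
    dose1_sq_dev = 0.0   # accumulators for the moment estimator of theta
    dose1_sq_mean = 0.0
    noise_allele_counts = []  # read counts of dose-0 (non-stutter) alleles
    n_locus_samples = 0
    stutter_points = {name: [] for name in locus_names}
    locus_totals = []

    for profile, counts in samples:
        doses = assign_dose(profile, counts)
        assigned = {name: counts.locus_total(name) for name in locus_names}
        total = sum(assigned.values())
        if total == 0:
            continue
        for name in locus_names:
            shares[name].append(assigned[name] / total)
            locus_totals.append(assigned[name])
        n_locus_samples += len(locus_names)
        for (sample, locus, allele), dose in doses.items():
            if dose != 0:
                continue
            # an n-1 neighbour of a true allele is stutter, not noise
            if panel[locus].kind == "STR":
                a, b = profile.genotypes[locus]
                if allele in {_stutter_parent_id(a), _stutter_parent_id(b)}:
                    continue
            noise_allele_counts.append(counts.counts[locus][allele])
        # dose-1 dispersion: paired heterozygous counts around their mean
        for locus, (a, b) in profile.genotypes.items():
            if a == b:
                continue
            d = counts.counts.get(locus, {})
            if a in d and b in d:
                c1, c2 = d[a], d[b]
                m = 0.5 * (c1 + c2)
                dose1_sq_dev += max(0.5 * (c1 - c2) ** 2 - m, 0.0)
                dose1_sq_mean += m * m
        # stutter observations
        if panel.kind == "STR":
            for locus, (a, b) in profile.genotypes.items():
                combined = counts.combined(locus)
                for parent in {a, b}:
                    target = _stutter_parent_id(parent)
                    if target is None or target in (a, b):
                        continue
                    parent_count = counts.counts.get(locus, {}).get(parent, 0)
                    if parent_count < 2 * threshold:
                        continue
                    ratio = combined.get(target, 0) / parent_count
                    stutter_points[locus].append((int(parent), ratio, parent_count))

    locus_efficiency = {
        name: float(np.mean(vals)) for name, vals in shares.items()
    }
    mean_share = float(np.mean(list(locus_efficiency.values())))
    locus_efficiency = {k: v / mean_share for k, v in locus_efficiency.items()}

    dispersion = (
        dose1_sq_mean / dose1_sq_dev if dose1_sq_dev > 0 else 1e6
    )
    dispersion = float(np.clip(dispersion, 1e-3, 1e6))

    noise_rate = len(noise_allele_counts) / n_locus_samples if n_locus_samples else 0.0
    noise_geom_p = _fit_geometric(noise_allele_counts, threshold)

    stutter_models = {}
    if panel.kind == "STR":
        pooled = [r for pts in stutter_points.values() for _, r, _ in pts]
        pooled_mean = float(np.mean(pooled)) if pooled else 0.0
        for name in locus_names:
            pts = stutter_points[name]
            if len(pts) >= 3:
                x = np.array([p for p, _, _ in pts], dtype=float)
                y = np.array([r for _, r, _ in pts], dtype=float)
                # ratio variance scales as 1/parent count -> WLS
                w = np.sqrt(np.array([c for _, _, c in pts], dtype=float))
                if np.ptp(x) > 0:
                    slope, intercept = np.polyfit(x, y, 1, w=w)
                else:
                    slope, intercept = 0.0, float(np.average(y, weights=w**2))
            else:
                slope, intercept = 0.0, pooled_mean
            stutter_models[name] = StutterModel(
                intercept=float(intercept), slope=float(slope), n_points=len(pts)
            )

    model = CalibrationModel(
        panel_kind=panel.kind,
        analytical_threshold=threshold,
        locus_efficiency=locus_efficiency,
        dispersion=dispersion,
        noise_rate=float(noise_rate),
        noise_geom_p=noise_geom_p,
        stutter_models=stutter_models,
        mean_locus_reads=float(np.mean(locus_totals)) if locus_totals else 0.0,
    )
    model.validate()
    return model
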