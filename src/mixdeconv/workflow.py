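"""End-to-end study orchestration at configurable scale.

The full design the package emulates: per assay (74-locus MH panel at
370,000 reads/sample; 26-locus STR panel at 220,000 reads/sample), 45
two-person mixtures per ratio (19:1, 9:1, 3:1, 1:1) and 56 three-person
mixtures per ratio (14:5:1, 14:3:3, 9:9:2); each mixture deconvoluted with
all-unknown hypotheses and additionally evaluated against 50 suspects of
which exactly one is a true contributor (the minor in two-person and 9:9:2
mixtures, the major in 14:3:3, the intermediate in 14:5:1).

``plan_experiment`` reproduces the full design arithmetic cheaply;
``run_experiment`` executes a configurable subset end to end (simulate ->
call -> calibrate -> deconvolute -> LR -> evaluate) with per-job result
files, making re-runs idempotent: a job whose result file matches the
config hash is not recomputed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel, calibrate
from .calling import AlleleCountTable, call_alleles
from .deconvolution import (
    Hypothesis,
    deconvolute,
    fit_hypothesis,
    likelihood_ratio,
)
from .evaluation import classify, contributor_ratio
from .mixtures import (
    THREE_PERSON_RATIOS,
    TWO_PERSON_RATIOS,
    build_three_person_design,
    build_two_person_design,
    mix,
)
from .panels import build_panel
from .population import sample_population, write_truth_tsv
from .reads import ReadGenerationParams, generate_reads
from .util import derive_seed

#: printed panel-wide depths of the two emulated assays
FULL_DEPTH = {"MH": 370_000, "STR": 220_000}
FULL_N_LOCI = {"MH": 74, "STR": 26}


@dataclass
class ExperimentConfig:
    """Scale and seeds of one study run.

    Defaults describe the full design; :func:`desk_scale_config` returns the
    reduced profile used for routine end-to-end runs.  ``depth_mh`` and
    ``depth_str`` default to the full assay depths scaled by the configured
    panel size, keeping per-locus coverage at the assay's level.
    """

    seed: int = 1
    out_dir: str = "results/study"
    panels: tuple = ("MH", "STR")
    n_loci_mh: int = 74
    n_loci_str: int = 26
    alleles_per_locus_mh: int = 5
    alleles_per_locus_str: int = 8
    population_size: int = 200
    n_donors: int = 10
    n_calibration: int = 50
    depth_mh: int | None = None
    depth_str: int | None = None
    two_person_ratios: tuple = TWO_PERSON_RATIOS
    three_person_ratios: tuple = THREE_PERSON_RATIOS
    pairs_per_ratio: dict = field(default_factory=dict)  # ratio -> count; {} = all 45
    triples_per_ratio: int = 56
    run_three_person: bool = False
    triples_per_ratio_run: int = 0  # executed three-person mixtures per ratio
    suspects_per_mixture: int = 50
    lr_mixtures_per_ratio: int = 0  # 0 = no LR stage
    lr_ratios: tuple = ("3:1",)
    lr_three_person_mixtures_per_ratio: int = 0

    def __post_init__(self):
        if self.suspects_per_mixture < 1:
            raise ValueError("suspects_per_mixture must be >= 1")
        if self.n_donors < 3:
            raise ValueError("need at least 3 donors")

    def n_loci(self, kind: str) -> int:
        return self.n_loci_mh if kind == "MH" else self.n_loci_str

    def depth(self, kind: str) -> int:
        explicit = self.depth_mh if kind == "MH" else self.depth_str
        if explicit is not None:
            return explicit
        return round(FULL_DEPTH[kind] * self.n_loci(kind) / FULL_N_LOCI[kind])

    def alleles_per_locus(self, kind: str) -> int:
        return self.alleles_per_locus_mh if kind == "MH" else self.alleles_per_locus_str

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("panels", "two_person_ratios", "three_person_ratios", "lr_ratios"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def full_scale_config(seed: int = 1) -> ExperimentConfig:
    return ExperimentConfig(
        seed=seed,
        run_three_person=True,
        triples_per_ratio_run=56,
        lr_mixtures_per_ratio=45,
        lr_ratios=TWO_PERSON_RATIOS,
        lr_three_person_mixtures_per_ratio=56,
    )


def desk_scale_config(seed: int = 1, out_dir: str = "results/study") -> ExperimentConfig:
    """Reduced study: 12 loci per panel, fewer mixtures, 10 suspects."""
    return ExperimentConfig(
        seed=seed,
        out_dir=out_dir,
        n_loci_mh=12,
        n_loci_str=12,
        n_calibration=20,
        pairs_per_ratio={"19:1": 8, "9:1": 8, "3:1": 8, "1:1": 20},
        suspects_per_mixture=10,
        lr_mixtures_per_ratio=4,
    )


@dataclass
class ExperimentManifest:
    """Closed-form job counts plus the enumerated designs."""

    config_hash: str
    n_panels: int
    two_person_mixtures: int
    three_person_mixtures: int
    two_person_lr_jobs: int
    three_person_lr_jobs: int
    total_lr_jobs: int
    two_person_noncontributor_jobs: int
    three_person_noncontributor_jobs: int
    three_person_true_contributor_jobs: int
    genotype_denominator: dict  # panel kind -> two-person genotype count
    pairs_per_ratio: dict
    triples_per_ratio: int
    designs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {k: v for k, v in asdict(self).items() if k != "designs"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def plan_experiment(config: ExperimentConfig) -> ExperimentManifest:
    """Enumerate the design and compute exact job counts."""
    n_panels = len(config.panels)
    n_pairs_full = math.comb(config.n_donors, 2)
    pairs_per_ratio = {
        r: min(config.pairs_per_ratio.get(r, n_pairs_full), n_pairs_full)
        for r in config.two_person_ratios
    }
    two_pp = sum(pairs_per_ratio.values())  # per panel
    two_total = two_pp * n_panels
    if config.run_three_person:
        n_triples = min(config.triples_per_ratio, math.comb(config.n_donors, 3))
        three_pp = n_triples * len(config.three_person_ratios)
    else:
        n_triples = 0
        three_pp = 0
    three_total = three_pp * n_panels

    s = config.suspects_per_mixture
    manifest = ExperimentManifest(
        config_hash=config.config_hash(),
        n_panels=n_panels,
        two_person_mixtures=two_total,
        three_person_mixtures=three_total,
        two_person_lr_jobs=two_total * s,
        three_person_lr_jobs=three_total * s,
        total_lr_jobs=(two_total + three_total) * s,
        two_person_noncontributor_jobs=two_total * (s - 1),
        three_person_noncontributor_jobs=three_total * (s - 1),
        three_person_true_contributor_jobs=three_total,
        genotype_denominator={
            kind: two_pp * config.n_loci(kind) * 2 for kind in config.panels
        },
        pairs_per_ratio=pairs_per_ratio,
        triples_per_ratio=n_triples,
    )
    return manifest


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


@dataclass
class PanelContext:
    """Everything one panel's mixtures share: panel, cohort, calibration."""

    kind: str
    panel: object
    freqs: object
    donors: list
    suspect_pool: list
    calib: CalibrationModel
    donor_readsets: dict


def build_panel_context(config: ExperimentConfig, kind: str) -> PanelContext:
    seed = config.seed
    panel = build_panel(kind, config.n_loci(kind), derive_seed(seed, kind, "panel"))
    freqs, population = sample_population(
        panel,
        config.alleles_per_locus(kind),
        config.population_size,
        derive_seed(seed, kind, "population"),
        sample_prefix=f"{kind}-IND",
    )
    donors = population[: config.n_donors]
    calib_cohort = population[config.n_donors : config.n_donors + config.n_calibration]
    suspect_pool = population[config.n_donors + config.n_calibration :]
    depth = config.depth(kind)

    calib_samples = []
    for prof in calib_cohort:
        params = ReadGenerationParams(
            total_reads=depth, seed=derive_seed(seed, kind, "calib", prof.sample_id)
        )
        counts = call_alleles(generate_reads(prof, panel, params), panel)
        calib_samples.append((prof, counts))
    calib = calibrate(calib_samples, panel)

    donor_readsets = {}
    for prof in donors:
        params = ReadGenerationParams(
            total_reads=depth, seed=derive_seed(seed, kind, "donor", prof.sample_id)
        )
        donor_readsets[prof.sample_id] = generate_reads(prof, panel, params)
    return PanelContext(
        kind=kind,
        panel=panel,
        freqs=freqs,
        donors=donors,
        suspect_pool=suspect_pool,
        calib=calib,
        donor_readsets=donor_readsets,
    )


def _job_path(out: Path, job_id: str) -> Path:
    return out / "jobs" / f"{job_id}.json"


def _load_job(out: Path, job_id: str, config_hash: str):
    path = _job_path(out, job_id)
    if path.exists():
        try:
            with open(path) as fh:
                payload = json.load(fh)
            if payload.get("config_hash") == config_hash:
                return payload
        except json.JSONDecodeError:
            return None
    return None


def _save_job(out: Path, job_id: str, payload: dict) -> None:
    path = _job_path(out, job_id)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _true_suspect_index(noc: int, ratio: str) -> int:
    """Contributor index of the true 'suspect' (roles follow ratio order).

    Two-person suspects are the minor contributor; three-person suspects
    are the minor in 9:9:2, the major in 14:3:3 and the intermediate in
    14:5:1.
    """
    if noc == 2:
        return -1
    return {"9:9:2": 2, "14:3:3": 0, "14:5:1": 1}.get(ratio, -1)


def _mixture_counts(config, ctx, spec, counts_dir, job_id):
    # the config hash keys the cache: a different configuration must never
    # reuse counts simulated under another panel or depth
    counts_path = counts_dir / f"{config.config_hash()[:8]}_{job_id}.tsv"
    if not counts_path.exists():
        sources = [ctx.donor_readsets[s] for s in spec.contributor_sample_ids]
        mixture = mix(sources, spec)
        counts = call_alleles(mixture, ctx.panel)
        counts.to_tsv(counts_path)
    return AlleleCountTable.from_tsv(counts_path)


def _run_design_jobs(config, ctx, specs, noc, out, chash, store, panel_store):
    """Deconvolute and score every mixture spec; jobs are cached and isolated."""
    kind = ctx.kind
    counts_dir = out / "counts"
    counts_dir.mkdir(exist_ok=True)
    donor_by_id = {p.sample_id: p for p in ctx.donors}
    for spec in specs:
        ratio = spec.label.split("/")[0]
        job_id = f"{kind}_deconv_{spec.label.replace('/', '_').replace('+', '-')}"
        cached = _load_job(out, job_id, chash)
        if cached is not None and cached.get("status") == "ok":
            payload = cached
        else:
            try:
                counts = _mixture_counts(config, ctx, spec, counts_dir, job_id)
                result = deconvolute(counts, noc, ctx.calib, ctx.freqs)
                truth = [donor_by_id[s] for s in spec.contributor_sample_ids]
                records = classify(
                    result, truth, spec.proportions, mixture_label=spec.label
                )
                payload = {
                    "config_hash": chash,
                    "status": "ok",
                    "label": spec.label,
                    "ratio": ratio,
                    "noc": noc,
                    "omega": list(result.fit.omega),
                    "estimated_ratio": contributor_ratio(result.fit.omega),
                    "records": [
                        [r.locus, r.contributor_rank, r.classification]
                        for r in records
                    ],
                    "call_details": [
                        [locus, rank, call.posterior, call.dropout,
                         len(counts.counts.get(locus, {})),
                         result.is_determinate(locus, rank)]
                        for locus, calls in result.calls.items()
                        for rank, call in enumerate(calls)
                    ],
                }
            except Exception as exc:  # noqa: BLE001 - jobs are isolated
                payload = {
                    "config_hash": chash,
                    "status": "failed",
                    "label": spec.label,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            _save_job(out, job_id, payload)
        if payload["status"] != "ok":
            store["failures"].append(payload)
            continue
        panel_store["n_two_person" if noc == 2 else "n_three_person"] += 1
        panel_store["records"].extend(
            {"label": payload["label"], "ratio": payload["ratio"],
             "locus": loc, "rank": rank, "classification": cls}
            for loc, rank, cls in payload["records"]
        )
        panel_store["proportions"].append(
            {"label": payload["label"], "ratio": payload["ratio"],
             "estimated_ratio": payload["estimated_ratio"]}
        )
        panel_store["call_details"][payload["label"]] = payload.get(
            "call_details", []
        )


def _run_lr_jobs(config, ctx, specs, noc, ratios, per_ratio, out, chash,
                 store, panel_store):
    """LR jobs: one true contributor plus fresh non-contributor suspects."""
    kind = ctx.kind
    counts_dir = out / "counts"
    counts_dir.mkdir(exist_ok=True)
    donor_by_id = {p.sample_id: p for p in ctx.donors}
    for ratio in ratios:
        lr_specs = [s for s in specs if s.label.startswith(f"{ratio}/")][:per_ratio]
        true_idx = _true_suspect_index(noc, ratio)
        for spec in lr_specs:
            true_suspect = donor_by_id[spec.contributor_sample_ids[true_idx]]
            rng = np.random.default_rng(
                derive_seed(config.seed, kind, "suspects", spec.label)
            )
            pool_idx = rng.choice(
                len(ctx.suspect_pool),
                size=config.suspects_per_mixture - 1,
                replace=False,
            )
            suspects = [("true", true_suspect)] + [
                ("non", ctx.suspect_pool[i]) for i in pool_idx
            ]
            job_id = f"{kind}_lr_{spec.label.replace('/', '_').replace('+', '-')}"
            cached = _load_job(out, job_id, chash)
            if cached is not None and cached.get("status") == "ok":
                panel_store["lr"].extend(cached["lrs"])
                continue
            try:
                deconv_job = (
                    f"{kind}_deconv_{spec.label.replace('/', '_').replace('+', '-')}"
                )
                counts = _mixture_counts(config, ctx, spec, counts_dir, deconv_job)
                fit_hd = fit_hypothesis(
                    counts, Hypothesis(noc=noc), ctx.calib, ctx.freqs
                )
                lrs = []
                for role, suspect in suspects:
                    lr = likelihood_ratio(
                        counts, suspect, noc, ctx.calib, ctx.freqs, fit_hd=fit_hd
                    )
                    lrs.append(
                        {"label": spec.label, "ratio": ratio, "role": role,
                         "noc": noc, "suspect": suspect.sample_id,
                         "log10_lr": lr.log10_lr
                         if np.isfinite(lr.log10_lr) else "-inf"}
                    )
                payload = {"config_hash": chash, "status": "ok", "lrs": lrs}
            except Exception as exc:  # noqa: BLE001
                payload = {
                    "config_hash": chash, "status": "failed",
                    "label": spec.label,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            _save_job(out, job_id, payload)
            if payload["status"] == "ok":
                panel_store["lr"].extend(payload["lrs"])
            else:
                store["failures"].append(payload)


def run_experiment(config: ExperimentConfig, manifest=None) -> dict:
    """Run the configured study; returns the in-memory result store.

    Results are additionally persisted under ``config.out_dir`` (one JSON
    per deconvolution/LR job keyed by a config hash, plus summary tables),
    so an interrupted or repeated run only computes missing jobs.  A job
    that fails is recorded with its error and does not stop the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "jobs").mkdir(exist_ok=True)
    chash = config.config_hash()
    if manifest is None:
        manifest = plan_experiment(config)
    manifest.to_json(out / "manifest.json")
    config.to_yaml(out / "config.yaml")

    store: dict = {"config_hash": chash, "panels": {}, "failures": []}
    for kind in config.panels:
        ctx = build_panel_context(config, kind)
        ctx.panel.to_json(out / f"panel_{kind}.json")
        ctx.freqs.to_tsv(out / f"freqs_{kind}.tsv")
        write_truth_tsv(ctx.donors, out / f"truth_{kind}.tsv")
        ctx.calib.save(out / f"calibration_{kind}.json")

        panel_store = {
            "records": [],
            "proportions": [],
            "lr": [],
            "call_details": {},
            "n_two_person": 0,
            "n_three_person": 0,
        }
        depth = config.depth(kind)
        donor_ids = [p.sample_id for p in ctx.donors]

        design2 = build_two_person_design(
            kind, donor_ids, depth, derive_seed(config.seed, kind, "design2"),
            ratios=config.two_person_ratios, cohort_size=config.n_donors,
        )
        specs2 = []
        n_pairs_full = math.comb(config.n_donors, 2)
        for ratio in config.two_person_ratios:
            cap = config.pairs_per_ratio.get(ratio, n_pairs_full)
            specs2.extend(design2.specs_for_ratio(ratio)[:cap])
        _run_design_jobs(config, ctx, specs2, 2, out, chash, store, panel_store)
        if config.lr_mixtures_per_ratio > 0:
            _run_lr_jobs(
                config, ctx, specs2, 2, config.lr_ratios,
                config.lr_mixtures_per_ratio, out, chash, store, panel_store,
            )

        if config.triples_per_ratio_run > 0:
            design3 = build_three_person_design(
                kind, donor_ids, depth, derive_seed(config.seed, kind, "design3"),
                ratios=config.three_person_ratios, cohort_size=config.n_donors,
                triples_per_ratio=min(
                    config.triples_per_ratio, math.comb(config.n_donors, 3)
                ),
            )
            specs3 = []
            for ratio in config.three_person_ratios:
                specs3.extend(
                    design3.specs_for_ratio(ratio)[: config.triples_per_ratio_run]
                )
            _run_design_jobs(config, ctx, specs3, 3, out, chash, store, panel_store)
            if config.lr_three_person_mixtures_per_ratio > 0:
                _run_lr_jobs(
                    config, ctx, specs3, 3, config.three_person_ratios,
                    config.lr_three_person_mixtures_per_ratio, out, chash,
                    store, panel_store,
                )

        store["panels"][kind] = panel_store
    _write_reports(config, store)
    return store


def _write_reports(config: ExperimentConfig, store: dict) -> None:
    out = Path(config.out_dir)
    for kind, ps in store["panels"].items():
        if ps["records"]:
            df = pd.DataFrame(ps["records"])
            df.to_csv(out / f"evaluation_records_{kind}.tsv", sep="\t", index=False)
        if ps["proportions"]:
            pd.DataFrame(ps["proportions"]).to_csv(
                out / f"proportions_{kind}.tsv", sep="\t", index=False
            )
        if ps["lr"]:
            pd.DataFrame(ps["lr"]).to_csv(
                out / f"lr_{kind}.tsv", sep="\t", index=False
            )


def report(store: dict) -> dict:
    """Summaries of a result store: error rates, LR separation, counts."""
    out: dict = {"panels": {}, "n_failures": len(store.get("failures", []))}
    for kind, ps in store["panels"].items():
        recs = ps["records"]
        total = len(recs)
        wrong = sum(1 for r in recs if r["classification"] == "Wrong")
        correct = sum(1 for r in recs if r["classification"] == "Correct")
        lr_true = [
            float(r["log10_lr"]) for r in ps["lr"]
            if r["role"] == "true" and r["log10_lr"] != "-inf"
        ]
        lr_non_finite = [
            float(r["log10_lr"]) for r in ps["lr"]
            if r["role"] == "non" and r["log10_lr"] != "-inf"
        ]
        n_neg_inf = sum(1 for r in ps["lr"] if r["log10_lr"] == "-inf")
        panel_report = {
            "n_two_person_mixtures": ps["n_two_person"],
            "genotypes_evaluated": total,
            "wrong": wrong,
            "correct": correct,
            "error_rate_pct": 100.0 * wrong / total if total else 0.0,
            "n_lr_jobs": len(ps["lr"]),
            "n_lr_neg_inf": n_neg_inf,
            "min_true_log10_lr": min(lr_true) if lr_true else None,
            "max_noncontributor_log10_lr": max(lr_non_finite)
            if lr_non_finite
            else None,
            "complete_lr_separation": bool(
                lr_true
                and (not lr_non_finite or min(lr_true) > max(lr_non_finite))
            ),
        }
        out["panels"][kind] = panel_report
    return out
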