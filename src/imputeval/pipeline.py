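"""End-to-end orchestration: simulate, ascertain, cross-validate, evaluate.

The pipeline reproduces an imputation-accuracy study design on
simulated data: a sequence-density marker set with nested hd-like and
lo-like panels, five-fold cross-validation under the S80/S60/S40 and
two-step reference schemes, per-SNP and per-individual accuracy, and
the reliability model fitted to the hd-panel results.

A single master seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence`` (spawn keys 0 = simulation, 1 = diploid
sampling, 2 = group assignment), so any stage can be rerun in
isolation and whole runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cv, evaluate, panels, reliability, vcfio
from .lshmm import LiStephensImputer, impute_stepwise
from .panels import PanelDefinition, build_panel, mask_to_panel
from .sim import (
    GenotypeMatrix,
    HaplotypeSet,
    SimulationConfig,
    sample_diploids,
    segregating_mask,
    simulate_population,
)

__all__ = [
    "RunConfig",
    "Dataset",
    "ScenarioResult",
    "prepare_dataset",
    "run_scenario",
    "run_two_step",
    "run_pipeline",
    "write_plan_tsv",
    "read_plan_tsv",
]


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one study run (JSON round-trippable)."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hd_size: int = 200
    lo_size: int = 20
    panel_maf_min: float = 0.05
    scenarios: tuple[str, ...] = ("S80", "S60", "S40", "TWO_STEP")
    n_folds: int = 5
    recombination_scale: float = 100.0
    error_rate: float = 1e-3
    ne_prediction: float = 1000.0
    dmaf_variant: str = "ratio_linear"
    master_seed: int = 1

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["scenarios"] = list(d["scenarios"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["sim"] = SimulationConfig(**d["sim"])
        d["scenarios"] = tuple(d["scenarios"])
        return cls(**d)


def _stage_seed(master_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class Dataset:
    """Sampled study individuals with their truth haplotypes.

    Haplotype rows ``2i`` and ``2i+1`` belong to individual ``i``; the
    marker set is restricted to sites segregating in the sample (the
    "sequence" panel).
    """

    genos: GenotypeMatrix
    haps: HaplotypeSet

    @property
    def n_individuals(self) -> int:
        return self.genos.n_individuals

    @property
    def n_markers(self) -> int:
        return self.genos.n_markers

    def hap_rows(self, individuals: np.ndarray) -> np.ndarray:
        individuals = np.asarray(individuals)
        return np.column_stack((2 * individuals, 2 * individuals + 1)).ravel()


def prepare_dataset(sim_cfg: SimulationConfig, master_seed: int | None = None) -> Dataset:
    """Simulate a population, sample study individuals, drop fixed sites."""
    if master_seed is not None:
        sim_cfg = dataclasses.replace(sim_cfg, seed=_stage_seed(master_seed, 0))
        sample_seed = _stage_seed(master_seed, 1)
    else:
        sample_seed = _stage_seed(sim_cfg.seed, 1)
    pop = simulate_population(sim_cfg)
    genos = sample_diploids(pop, sim_cfg.n_sample_individuals, seed=sample_seed)
    hap_rows = genos.source_hap_indices.ravel()
    haps = pop.take_haplotypes(hap_rows)
    seg = np.flatnonzero(segregating_mask(genos))
    genos = genos.take_markers(seg)
    haps = haps.take_markers(seg)
    n = genos.n_individuals
    genos.source_hap_indices = np.arange(2 * n).reshape(n, 2)
    return Dataset(genos=genos, haps=haps)


@dataclass
class ScenarioResult:
    """Accuracy results for one scenario x panel combination."""

    scenario: str
    panel_name: str
    dosages: np.ndarray
    eval_marker_indices: np.ndarray
    kept_marker_indices: np.ndarray
    n_markers_removed: int
    per_snp_r: np.ndarray
    per_individual: pd.DataFrame
    validation_groups: list[np.ndarray]

    @property
    def mean_per_snp(self) -> float:
        return float(np.mean(self.per_snp_r))

    @property
    def mean_per_individual(self) -> float:
        return float(np.nanmean(self.per_individual["raw"].to_numpy()))

    def summary_row(self) -> dict:
        r = self.per_snp_r
        return {
            "scenario": self.scenario,
            "panel": self.panel_name,
            "mean": round(float(np.mean(r)), 3),
            "sd": round(float(np.std(r, ddof=1)), 3) if len(r) > 1 else float("nan"),
            "min": round(float(np.min(r)), 3),
            "max": round(float(np.max(r)), 3),
            "n_snps": int(len(r)),
        }


def _group_indices(
    assignment: cv.GroupAssignment, ids: list[str]
) -> np.ndarray:
    return np.array([assignment.group_of[i] for i in ids])


def _evaluate(
    ds: Dataset,
    dosages: np.ndarray,
    eval_idx: np.ndarray,
    validation_groups: list[np.ndarray],
    scenario: str,
    panel_name: str,
    observed: np.ndarray | None = None,
) -> ScenarioResult:
    obs_all = ds.genos.genotypes if observed is None else observed
    obs = obs_all[:, eval_idx].astype(float)
    dos = dosages[:, eval_idx]
    keep = evaluate.filter_informative(obs, dos, validation_groups)
    kept_idx = eval_idx[keep]
    per_snp = evaluate.accuracy_per_snp_matrix(obs[:, keep], dos[:, keep])

    rows = []
    for g, members in enumerate(validation_groups, start=1):
        ok = obs[members][:, keep]
        means = ok.mean(axis=0)
        sds = ok.std(axis=0)
        for i in members:
            o = obs[i, keep]
            d = dos[i, keep]
            rows.append(
                {
                    "individual_id": None,
                    "individual_index": int(i),
                    "fold": g,
                    "raw": evaluate.accuracy_per_individual(o, d, "raw"),
                    "centered": evaluate.accuracy_per_individual(
                        o, d, "centered", marker_means=means
                    ),
                    "standardized": evaluate.accuracy_per_individual(
                        o, d, "standardized", marker_means=means, marker_sds=sds
                    ),
                }
            )
    per_ind = pd.DataFrame(rows)
    per_ind["individual_id"] = [
        ds.genos.individual_ids[i] for i in per_ind["individual_index"]
    ]
    return ScenarioResult(
        scenario=scenario,
        panel_name=panel_name,
        dosages=dosages,
        eval_marker_indices=eval_idx,
        kept_marker_indices=kept_idx,
        n_markers_removed=int(len(eval_idx) - len(kept_idx)),
        per_snp_r=per_snp,
        per_individual=per_ind,
        validation_groups=validation_groups,
    )


def run_scenario(
    ds: Dataset,
    panel: PanelDefinition,
    assignment: cv.GroupAssignment,
    scenario: str,
    recombination_scale: float = 100.0,
    error_rate: float = 1e-3,
) -> ScenarioResult:
    """Impute every fold of a single-step scenario and evaluate.

    Each individual is imputed exactly once (as a member of its
    validation group); per-SNP accuracy pools all individuals, which is
    how one value per SNP per scenario arises from five folds.
    Accuracy is evaluated at masked (non-panel) markers only.
    """
    plan = cv.build_plan(scenario, k=assignment.k)
    groups = _group_indices(assignment, ds.genos.individual_ids)
    dosages = np.full(ds.genos.genotypes.shape, np.nan)
    validation_groups = []
    for fold in plan.folds:
        val = np.flatnonzero(groups == fold.validation_group)
        ref = np.flatnonzero(np.isin(groups, fold.reference_groups))
        ref_haps = ds.haps.take_haplotypes(ds.hap_rows(ref))
        targets = mask_to_panel(_take_individuals(ds.genos, val), panel)
        imputer = LiStephensImputer(
            recombination_scale=recombination_scale, error_rate=error_rate
        ).fit(ref_haps)
        dosages[val] = imputer.predict(targets).dosages
        validation_groups.append(val)
    eval_idx = np.setdiff1d(np.arange(ds.n_markers), panel.marker_indices)
    return _evaluate(ds, dosages, eval_idx, validation_groups, scenario, panel.name)


def run_two_step(
    ds: Dataset,
    lo: PanelDefinition,
    hd: PanelDefinition,
    assignment: cv.GroupAssignment,
    recombination_scale: float = 100.0,
    error_rate: float = 1e-3,
) -> dict[str, ScenarioResult]:
    """Two-step scenario: lo -> hd (step 1), hd -> sequence (step 2).

    Returns step-level and overall results keyed ``step1`` (evaluated at
    hd-not-lo markers on the hd lattice), ``step2`` (sequence-not-hd)
    and ``overall`` (sequence-not-lo).
    """
    plan = cv.build_plan("TWO_STEP", k=assignment.k)
    groups = _group_indices(assignment, ds.genos.individual_ids)
    dosages = np.full(ds.genos.genotypes.shape, np.nan)
    hd_dosages = np.full((ds.n_individuals, len(hd)), np.nan)
    validation_groups = []
    for fold in plan.folds:
        val = np.flatnonzero(groups == fold.validation_group)
        ref1 = np.flatnonzero(np.isin(groups, fold.step1_reference_groups))
        ref2 = np.flatnonzero(np.isin(groups, fold.step2_reference_groups))
        targets = mask_to_panel(_take_individuals(ds.genos, val), lo)
        final, step1 = impute_stepwise(
            targets,
            ds.haps.take_haplotypes(ds.hap_rows(ref1)),
            ds.haps.take_haplotypes(ds.hap_rows(ref2)),
            lo,
            hd,
            recombination_scale=recombination_scale,
            error_rate=error_rate,
        )
        dosages[val] = final.dosages
        hd_dosages[val] = step1.dosages
        validation_groups.append(val)

    seq_idx = np.arange(ds.n_markers)
    overall = _evaluate(
        ds, dosages, np.setdiff1d(seq_idx, lo.marker_indices),
        validation_groups, "TWO_STEP", "overall",
    )
    step2 = _evaluate(
        ds, dosages, np.setdiff1d(seq_idx, hd.marker_indices),
        validation_groups, "TWO_STEP", "step2",
    )
    # step 1 lives on the hd marker lattice
    hd_obs = ds.genos.genotypes[:, hd.marker_indices]
    lo_within_hd = np.flatnonzero(np.isin(hd.marker_indices, lo.marker_indices))
    step1_eval = np.setdiff1d(np.arange(len(hd)), lo_within_hd)
    step1_res = _evaluate(
        ds, hd_dosages, step1_eval, validation_groups, "TWO_STEP", "step1",
        observed=hd_obs,
    )
    return {"step1": step1_res, "step2": step2, "overall": overall}


def _take_individuals(genos: GenotypeMatrix, rows: np.ndarray) -> GenotypeMatrix:
    rows = np.asarray(rows)
    return GenotypeMatrix(
        genotypes=genos.genotypes[rows],
        marker_map=genos.marker_map,
        individual_ids=[genos.individual_ids[i] for i in rows],
    )


def write_plan_tsv(path, plan: cv.ScenarioPlan, assignment: cv.GroupAssignment) -> None:
    rows = []
    for fold in plan.folds:
        roles = [("validation", (fold.validation_group,))]
        if fold.reference_groups:
            roles.append(("reference", fold.reference_groups))
        if fold.step1_reference_groups:
            roles.append(("step1_reference", fold.step1_reference_groups))
        if fold.step2_reference_groups:
            roles.append(("step2_reference", fold.step2_reference_groups))
        for role, grps in roles:
            for g in grps:
                for ind in assignment.members(g):
                    rows.append(
                        {
                            "fold": fold.validation_group,
                            "role": role,
                            "group": g,
                            "individual_id": ind,
                        }
                    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plan_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full study and write all artifacts under ``outdir``.

    Stages: simulate -> sample -> panels -> plans -> impute every
    scenario (including two-step) -> accuracy -> reliability model.
    Returns a dict of in-memory results; files written: truth VCF,
    marker map TSV, panel TSVs, plan TSVs, per-marker and per-individual
    results TSVs, summary TSV (scenario x panel x mean/SD/min/max/N),
    Michaelis-Menten fits JSON, and a run log.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"master_seed={config.master_seed}"]

    def _stage(name):
        log_lines.append(f"stage={name}")

    try:
        _stage("simulate")
        ds = prepare_dataset(config.sim, master_seed=config.master_seed)
        vcfio.write_haplotype_vcf(out / "truth.vcf", ds.haps)
        vcfio.write_marker_map_tsv(out / "markers.tsv", ds.genos.marker_map)
        log_lines.append(
            f"n_individuals={ds.n_individuals} n_segregating={ds.n_markers}"
        )

        _stage("panels")
        hd = build_panel(
            ds.genos.marker_map, ds.genos, config.panel_maf_min,
            config.hd_size, name="hd",
        )
        lo = build_panel(
            ds.genos.marker_map, ds.genos, config.panel_maf_min,
            config.lo_size, name="lo", within=hd,
        )
        vcfio.write_panel_tsv(out / "panel_hd.tsv", hd)
        vcfio.write_panel_tsv(out / "panel_lo.tsv", lo)

        _stage("plan")
        assignment = cv.assign_groups(
            list(ds.genos.individual_ids), k=config.n_folds,
            seed=_stage_seed(config.master_seed, 2),
        )
        for sc in config.scenarios:
            write_plan_tsv(
                out / f"plan_{sc}.tsv", cv.build_plan(sc, k=config.n_folds), assignment
            )

        _stage("impute+evaluate")
        results: dict[tuple[str, str], ScenarioResult] = {}
        for sc in config.scenarios:
            if sc == "TWO_STEP":
                for key, res in run_two_step(
                    ds, lo, hd, assignment,
                    recombination_scale=config.recombination_scale,
                    error_rate=config.error_rate,
                ).items():
                    results[(sc, key)] = res
            else:
                for panel in (hd, lo):
                    results[(sc, panel.name)] = run_scenario(
                        ds, panel, assignment, sc,
                        recombination_scale=config.recombination_scale,
                        error_rate=config.error_rate,
                    )

        summary = pd.DataFrame([r.summary_row() for r in results.values()])
        summary.to_csv(out / "summary_per_snp.tsv", sep="\t", index=False)
        ind_rows = []
        for (sc, pn), r in results.items():
            df = r.per_individual.copy()
            df.insert(0, "scenario", sc)
            df.insert(1, "panel", pn)
            ind_rows.append(df)
        pd.concat(ind_rows).to_csv(
            out / "per_individual.tsv", sep="\t", index=False, float_format="%.4f"
        )

        _stage("reliability")
        mm_fits = {}
        reliability_frames = []
        for sc in ("S40", "S60", "S80"):
            if (sc, "hd") not in results:
                continue
            res = results[(sc, "hd")]
            stats = evaluate.compute_marker_stats(
                ds.genos.marker_map, hd, ds.genos,
                marker_indices=res.kept_marker_indices,
            )
            bin_size = max(10, min(1000, len(res.per_snp_r) // 10))
            bins = evaluate.bin_by_covariate(
                res.per_snp_r, stats.maf, bin_size=bin_size,
                positions=res.kept_marker_indices,
            )
            fit = reliability.fit_michaelis_menten(
                bins["covariate_mean"].to_numpy(), bins["reliability_mean"].to_numpy()
            )
            mm_fits[sc] = {
                "Vmax": fit.Vmax_, "Km": fit.Km_,
                "Vmax_se": fit.Vmax_se_, "Km_se": fit.Km_se_,
                "n_bins": fit.n_bins_,
                "r2_maf_at_0.5": round(reliability.mm_value(fit.Vmax_, fit.Km_, 0.5), 3),
            }
            pred = reliability.predict_reliability(
                stats, fit, ne=config.ne_prediction, variant=config.dmaf_variant
            )
            pred.insert(0, "scenario", sc)
            pred["observed_r"] = res.per_snp_r
            pred["observed_r2"] = res.per_snp_r**2
            reliability_frames.append(pred)
        with open(out / "mm_fits.json", "w") as fh:
            json.dump(mm_fits, fh, indent=2, sort_keys=True)
        if reliability_frames:
            pd.concat(reliability_frames).to_csv(
                out / "reliability_per_marker.tsv", sep="\t",
                index=False, float_format="%.6g",
            )
    except Exception as err:
        stage = log_lines[-1] if log_lines else "?"
        raise RuntimeError(f"pipeline failed at {stage}: {err}") from err

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "config.json").write_text(config.to_json())
    return {
        "dataset": ds,
        "panels": {"hd": hd, "lo": lo},
        "assignment": assignment,
        "results": results,
        "summary": summary,
        "mm_fits": mm_fits,
    }
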