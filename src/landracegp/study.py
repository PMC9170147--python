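"""End-to-end synthetic study runner.

``run_study`` reproduces the full comparison of the pure (DH) and admixed
(gamete capture) approaches on synthetic data: genome and landrace
simulation, population derivation, closed-form expectations vs simulated
moments, molecular diversity statistics, multi-environment trials with
REML analysis, and genomic-prediction cross-validation.  Everything flows
from a single master seed through ``numpy.random.SeedSequence`` spawning,
so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, gblup, genome, populations, traits, trials
from .populations import PopType

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    """Configuration of a synthetic pure-vs-admixed study.

    Population sizes default to the reference design (LS 48, DH 471, GC 274
    per landrace); genome and scenario sizes default to desk scale.
    """

    # genome
    n_chrom: int = 10
    markers_per_chrom: int = 200
    chrom_length_cm: float = 150.0
    chrom_length_bp: float = 150e6
    pool_size: int = 400
    burnin_generations: int = 20
    freq_spectrum: str = "beta_u"
    private_fraction: float = 0.03
    # populations
    n_ls: int = 48
    n_dh: int = 471
    n_gc: int = 274
    # trait
    n_qtl: int = 200
    dominance_d12: float = 0.0
    dominance_d2x_private: float = 0.0
    # trials
    n_env: int = 4
    n_rep: int = 2
    target_h2: float = 0.9
    # prediction scenarios
    cv_n_lines: tuple = (50, 100, 150, 200, 250)
    cv_reps: int = 5
    cv_repeats: int = 2
    census_reps: int = 50
    ld_gametes: int = 94
    # master seed
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "cv_n_lines" in raw:
            raw["cv_n_lines"] = tuple(raw["cv_n_lines"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: StudyConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run_study(config: StudyConfig, outdir) -> dict:
    """Run the full synthetic study; returns the result bundle and writes CSVs."""
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(10)
    stage = "setup"
    results: dict = {}
    try:
        # --- genome and populations -----------------------------------------
        stage = "genome"
        gmap = genome.make_genetic_map(
            cfg.n_chrom, cfg.markers_per_chrom, cfg.chrom_length_cm, cfg.chrom_length_bp,
            seed=seeds[0],
        )
        pool = genome.simulate_ancestral_pool(
            gmap, cfg.pool_size, cfg.freq_spectrum, cfg.burnin_generations, seed=seeds[1]
        )
        capture, pool = genome.make_capture_line(pool, cfg.private_fraction, seed=seeds[2])
        p = pool.p.copy()

        stage = "populations"
        rng_pop = np.random.default_rng(seeds[3])
        ls = genome.sample_plants(pool, cfg.n_ls, seed=rng_pop.integers(2**31))
        dh = populations.derive_dh(pool, cfg.n_dh, rng_pop)
        s0, s1 = populations.derive_gc(pool, capture, cfg.n_gc, rng_pop)

        stage = "trait"
        trait = traits.assign_trait(
            gmap, p, cfg.n_qtl,
            dominance_spec={"d12": cfg.dominance_d12 or None,
                            "d2x_private": cfg.dominance_d2x_private or None},
            seed=seeds[4], private_loci=capture.private_loci,
        )
        report = traits.expected_population_stats(trait, p)

        # --- theory vs simulation -------------------------------------------
        stage = "expectations"
        sim_rows = []
        values = {
            "LS": traits.genotypic_value_pp(ls, trait),
            "DH": traits.genotypic_value_pp(dh, trait),
            "GC_S1_2": traits.true_entry_values(s1, trait, level="PP"),
        }
        tp_values = {
            "LS": traits.genotypic_value_tp(ls, trait),
            "DH": traits.genotypic_value_tp(dh, trait),
            "GC_S1_2": traits.genotypic_value_tp(s1, trait),
        }
        for popname in ("LS", "DH", "GC_S1_2"):
            for level, vals in (("PP", values[popname]), ("TP", tp_values[popname])):
                row = report.row(popname, level)
                sim_rows.append(
                    {
                        "population": popname,
                        "level": level,
                        "expected_mean": row["mean"],
                        "simulated_mean": float(np.mean(vals)),
                        "expected_primary_variance": row["primary"],
                        "simulated_variance": float(np.var(vals, ddof=1)),
                    }
                )
        theory_sim = pd.DataFrame(sim_rows)
        theory_sim["mean_delta"] = theory_sim["simulated_mean"] - theory_sim["expected_mean"]
        theory_sim["variance_ratio"] = (
            theory_sim["simulated_variance"] / theory_sim["expected_primary_variance"]
        )
        _write(theory_sim, outdir / "theory_vs_simulation.csv", cfg)
        _write(report.table, outdir / "expectations.csv", cfg)
        results["theory_vs_simulation"] = theory_sim
        results["expectations"] = report

        # --- diversity statistics -------------------------------------------
        stage = "diversity"
        pops = {"LS": ls, "DH": dh, "GC": s1}
        census = diversity.polymorphism_census(
            pops, n_gametes=min(80, 2 * cfg.n_ls), n_reps=cfg.census_reps,
            seed=seeds[5],
        )
        _write(census, outdir / "polymorphism_census.csv", cfg)
        thr_mol, thr_gen = traits.variance_thresholds()
        div_rows = []
        for name, popobj in pops.items():
            mv = diversity.molecular_variance(popobj)
            ld = diversity.ld_pairs(popobj.gametes(), gmap, n_gametes=cfg.ld_gametes,
                                    seed=seeds[5])
            fitd = diversity.fit_ld_decay(ld, cfg.ld_gametes) if len(ld) >= 10 else None
            if cfg.n_chrom > 1:
                xr2, _ = diversity.cross_chromosome_ld(popobj.gametes(), gmap, seed=seeds[5])
            else:
                xr2 = float("nan")
            div_rows.append(
                {
                    "population": name,
                    "mean_molecular_variance": float(mv.per_locus.mean()),
                    "amova_within": mv.var_within,
                    "amova_between": mv.var_between,
                    "ld_decay_delta_kb": fitd.delta_kb if fitd else float("nan"),
                    "cross_chrom_mean_r2": xr2,
                }
            )
        diversity_table = pd.DataFrame(div_rows)
        diversity_table["threshold_gc_vs_ls"] = thr_mol
        diversity_table["threshold_gc_vs_dh"] = thr_gen
        _write(diversity_table, outdir / "diversity.csv", cfg)
        lps = diversity.linkage_phase_similarity(dh.gametes(), s1.gametes(), gmap)
        _write(lps, outdir / "lps_dh_vs_gc.csv", cfg)
        results["diversity"] = diversity_table
        results["census"] = census

        # --- field trials -----------------------------------------------------
        stage = "trials"
        entry_values = np.concatenate([values["DH"], values["GC_S1_2"]])
        tags = np.array(["DH"] * cfg.n_dh + ["GC"] * cfg.n_gc)
        trial_data = trials.simulate_trials(
            entry_values, E=cfg.n_env, R=cfg.n_rep, target_h2=cfg.target_h2,
            seed=seeds[6], population=tags,
        )
        fit = trials.TrialModel(trial_data).fit()
        comp = fit.components_frame()
        _write(comp, outdir / "variance_components.csv", cfg)
        results["trial_fit"] = fit

        # --- genomic prediction ----------------------------------------------
        stage = "prediction"
        blues = fit.blues
        dose_dh = dh.dosage().astype(float)
        dose_gc = s1.dosage().astype(float)
        h2 = {name: fit.heritability(name)[0] for name in ("DH", "GC")}
        y_dh = blues.iloc[: cfg.n_dh].to_numpy()
        y_gc = blues.iloc[cfg.n_dh :].to_numpy()
        rng_cv = np.random.default_rng(seeds[7])
        cv_rows = []
        for n_lines in cfg.cv_n_lines:
            for name, y, dose in (("DH", y_dh, dose_dh), ("GC", y_gc, dose_gc)):
                if n_lines > len(y):
                    continue
                res = gblup.cv_within(
                    y, dose, h2[name], n_lines=n_lines, reps=cfg.cv_reps,
                    cv_repeats=cfg.cv_repeats, seed=rng_cv.integers(2**31),
                )
                cv_rows.append({"population": name, **res.summary_row()})
        across = gblup.cv_across(
            y_dh, dose_dh, y_gc, dose_gc, h2["GC"],
            n_train=min(200, len(y_dh)), n_predict=min(50, len(y_gc)),
            reps=cfg.cv_reps, seed=rng_cv.integers(2**31),
            scenario_label="across DH->GC",
        )
        cv_rows.append({"population": "DH->GC", **across.summary_row()})
        cv_table = pd.DataFrame(cv_rows)
        _write(cv_table, outdir / "prediction_accuracy.csv", cfg)
        results["prediction"] = cv_table
    except Exception as err:  # structured stage error, partial outputs remain on disk
        raise RuntimeError(f"study failed at stage {stage!r}: {err}") from err

    cfg.to_yaml(outdir / "config.yaml")
    results["config"] = cfg
    results["outdir"] = outdir
    return results
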