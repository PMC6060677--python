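"""Config-driven orchestration of the full analysis graph.

``run_pipeline`` executes: simulate-or-load -> region exclusion/removal ->
PQN -> RSPA -> per-model O-PLS-DA fit -> cross-validated Q2 + permutation
validation -> per-variable loading significance -> STOCSY on the top
loading -> univariate battery (t-test on log AL, chi-square on gender,
geometric-mean CIs, gender-adjusted logistic regression) -> versioned JSON
report.  Every stage logs its parameters and seeds; the run is idempotent
given a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import preprocess as prep
from . import simulate as sim
from . import spectra_io as sio
from . import stats as st
from . import validation as val
from .oplsda import backscaled_loadings, fit_opls_da, make_class_vector

__all__ = ["PipelineConfig", "demo_config", "run_pipeline"]

log = logging.getLogger("nmrmetab")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :func:`demo_config` for shape)."""

    seed: int
    models: list[dict]
    simulate: dict | None = None
    input: dict | None = None
    preprocess: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    out_dir: str | None = None
    stocsy_top: int = 10
    max_report_variables: int = 50

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ValueError("config needs exactly one of 'simulate' or 'input'")
        if not self.models:
            raise ValueError("config defines no models")
        for m in self.models:
            for key in ("name", "class_a", "class_b"):
                if key not in m:
                    raise ValueError(f"model definition missing {key!r}: {m}")
            m.setdefault("n_orth", 0)
        v = self.validation
        v.setdefault("k_folds", 7)
        v.setdefault("n_perm_model", 199)
        v.setdefault("n_perm_loadings", 499)
        v.setdefault("alpha", 0.05)
        p = self.preprocess
        p.setdefault("exclude", ["4.7:4.9"])
        p.setdefault("remove", [])
        p.setdefault("pqn", "median")
        p.setdefault("align", "rspa")
        p.setdefault("align_params", {})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        if "seed" not in d:
            raise ValueError("config must set 'seed' (reproducibility is mandatory)")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config(seed: int = 1, out_dir: str | None = None) -> PipelineConfig:
    """Bundled demonstration config: a synthetic cohort with the human
    cohort's class sizes (34 cases, 18 household and 17 village controls)
    and three two-class models, at reduced permutation counts."""
    return PipelineConfig.from_dict(
        {
            "seed": seed,
            "out_dir": out_dir,
            "simulate": {
                "n_per_class": {"case": 34, "household_control": 18, "village_control": 17},
                "effect_map": {
                    "case": {
                        "hippurate": 0.67,
                        "p-cresol sulphate": 0.70,
                        "tyrosine": 1.35,
                        "N-methylnicotinamide": 1.40,
                        "formate": 1.35,
                        "bile acids": 1.40,
                    },
                    "household_control": {
                        "tyrosine": 1.40,
                        "p-cresol sulphate": 0.67,
                        "3-HPPA": 0.75,
                    },
                },
            },
            "preprocess": {
                "exclude": ["4.7:4.9"],
                "remove": [],
                "pqn": "median",
                "align": "rspa",
                "align_params": {"n_iter": 1},
            },
            # n_orth matched to the simulated cohort's shared-variance
            # structure; on real data use the 2-3 components such studies fix
            "models": [
                {"name": "case_vs_village", "class_a": "case", "class_b": "village_control", "n_orth": 5},
                {"name": "case_vs_household", "class_a": "case", "class_b": "household_control", "n_orth": 5},
                {"name": "household_vs_village", "class_a": "household_control", "class_b": "village_control", "n_orth": 5},
            ],
            "validation": {"k_folds": 7, "n_perm_model": 199, "n_perm_loadings": 499, "alpha": 0.05},
        }
    )


def _derived_seeds(base: int, idx: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence([int(base), int(idx)])
    return [int(s % (2**31 - 1)) for s in ss.generate_state(n)]


def _load_or_simulate(config: PipelineConfig):
    if config.simulate is not None:
        d = dict(config.simulate)
        d.setdefault("seed", config.seed)
        if "ppm_range" in d:
            d["ppm_range"] = tuple(d["ppm_range"])
        design = sim.CohortDesign(**d)
        log.info("simulate: %s samples, grid %d points, seed %d",
                 design.n_per_class, design.n_points, design.seed)
        matrix, table, truth = sim.simulate_cohort(design)
        return matrix, table, truth
    spectra_path = config.input["spectra"]
    meta_path = config.input["metadata"]
    log.info("load: spectra=%s metadata=%s", spectra_path, meta_path)
    return sio.read_spectra(spectra_path), sio.read_sample_table(meta_path), None


def _preprocess(matrix: sio.SpectraMatrix, opts: dict):
    regions = prep.RegionSet.from_strings(list(opts["exclude"]) + list(opts["remove"]))
    if regions.regions:
        matrix = prep.exclude_regions(matrix, regions)
        log.info("exclude: %s -> %d columns", regions.regions, matrix.n_points)
    quotients = None
    if opts["pqn"]:
        matrix, quotients = prep.pqn_normalize(matrix, reference=opts["pqn"])
        log.info("pqn: reference=%s", opts["pqn"])
    if opts["align"] == "rspa":
        params = prep.AlignmentParams(**opts["align_params"])
        matrix, shift_map = prep.rspa_align(matrix, params=params)
        moved = sum(1 for segs in shift_map.values() for *_, s in segs if s != 0)
        log.info("rspa: %d segment shifts applied", moved)
    elif opts["align"] not in (None, "none", ""):
        raise ValueError(f"unknown align option {opts['align']!r}")
    return matrix, quotients


def _univariate_block(table: sio.SampleTable, ids_a: list[str], ids_b: list[str],
                      class_a: str, class_b: str) -> dict:
    out: dict = {}
    al_a = np.asarray(table.column_for(ids_a, "al_level"), dtype=float)
    al_b = np.asarray(table.column_for(ids_b, "al_level"), dtype=float)
    al_a, al_b = al_a[np.isfinite(al_a)], al_b[np.isfinite(al_b)]
    if al_a.size >= 2 and al_b.size >= 2 and (al_a > 0).all() and (al_b > 0).all():
        tt = st.t_test(al_a, al_b, log_transform=True, tail="one")
        gm_a = st.geometric_mean_ci(al_a)
        gm_b = st.geometric_mean_ci(al_b)
        out["al_log_t_test"] = {"t": tt.statistic, "p": tt.p_value, "tail": tt.tail}
        out["al_geometric_mean"] = {
            class_a: {"gm": gm_a[0], "ci": [gm_a[1], gm_a[2]]},
            class_b: {"gm": gm_b[0], "ci": [gm_b[1], gm_b[2]]},
        }
    g_a = table.column_for(ids_a, "gender")
    g_b = table.column_for(ids_b, "gender")
    tab = np.array(
        [
            [int(np.sum(g_a == "M")), int(np.sum(g_a == "F"))],
            [int(np.sum(g_b == "M")), int(np.sum(g_b == "F"))],
        ]
    )
    if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
        cs = st.chi_square(tab)
        out["gender_chi2"] = {"chi2": cs.statistic, "p": cs.p_value, "table": tab.tolist()}
    return out


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns the report dict and writes files when
    an output directory is configured."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None

    matrix, table, truth = _load_or_simulate(config)

    # validate model class labels before any computation
    counts = table.class_counts()
    for m in config.models:
        for cls in (m["class_a"], m["class_b"]):
            if counts.get(cls, 0) == 0:
                raise ValueError(
                    f"model {m['name']!r} references class {cls!r} absent from the "
                    f"sample table (present: {sorted(counts)})"
                )

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if truth is not None:
            sio.write_spectra(matrix, out / "spectra_raw.csv")
            sio.write_sample_table(table, out / "sample_table.csv")
            truth.to_json(out / "ground_truth.json")

    matrix, _ = _preprocess(matrix, config.preprocess)
    labels = table.labels_for(matrix.sample_ids)
    vcfg = config.validation

    summaries, validations = [], []
    for idx, m in enumerate(config.models):
        seeds = _derived_seeds(config.seed, idx)
        mask, cv_y = make_class_vector(labels, m["class_a"], m["class_b"])
        ids = [s for s, keep in zip(matrix.sample_ids, mask) if keep]
        X = matrix.intensities[mask]
        y = cv_y.y
        n_a, n_b = int(y.sum()), int((1 - y).sum())
        log.info("model %s: %s (%d) vs %s (%d), n_orth=%d",
                 m["name"], m["class_a"], n_a, m["class_b"], n_b, m["n_orth"])

        state = prep.fit_scaler(X)
        Xs = prep.apply_scaler(X, state)
        ppm_kept = matrix.ppm[state.kept_columns]
        model = fit_opls_da(Xs, y, n_orth=m["n_orth"], scaling_state=state)

        cv = val.cross_validate_q2(X, y, n_orth=m["n_orth"],
                                   k_folds=vcfg["k_folds"], seed=seeds[0])
        perm = val.permutation_test_model(
            X, y, n_orth=m["n_orth"], n_perm=vcfg["n_perm_model"],
            k_folds=vcfg["k_folds"], seed=seeds[1])
        loadsig = val.permutation_test_loadings(
            X, y, n_orth=m["n_orth"], n_perm=vcfg["n_perm_loadings"],
            alpha=vcfg["alpha"], seed=seeds[2])

        profile = backscaled_loadings(model, state, ppm=ppm_kept)
        order = np.argsort(-profile.abs_r)
        sig_idx = [int(j) for j in order if loadsig.significant[j]]
        sig_vars = [
            {"ppm": float(ppm_kept[j]), "r": float(model.loading_r[j]),
             "p": float(loadsig.p_values[j])}
            for j in sig_idx[: config.max_report_variables]
        ]

        top_j = int(order[0])
        sr = st.stocsy(X, matrix.ppm, float(ppm_kept[top_j]))
        top_corr = np.argsort(-np.abs(sr.r))[: config.stocsy_top]
        stocsy_block = {
            "driver_ppm": sr.driver_ppm,
            "top_correlated": [
                {"ppm": float(matrix.ppm[j]), "r": float(sr.r[j])} for j in top_corr
            ],
        }

        uni = _univariate_block(table, [s for s, yy in zip(ids, y) if yy == 1],
                                [s for s, yy in zip(ids, y) if yy == 0],
                                m["class_a"], m["class_b"])
        gender = table.column_for(ids, "gender")
        if len(set(gender)) == 2 and len(ids) >= 10:
            try:
                lg = st.logistic_adjusted(y, X[:, state.kept_columns[top_j]],
                                          (gender == "M").astype(float))
                uni["logistic_gender_adjusted"] = {
                    "separation": lg.separation,
                    "converged": lg.converged,
                    "beta": None if lg.params is None else [float(v) for v in lg.params],
                    "p": None if lg.p_values is None else [float(v) for v in lg.p_values],
                }
            except ValueError as exc:
                uni["logistic_gender_adjusted"] = {"error": str(exc)}

        summaries.append(
            {
                "name": m["name"],
                "class_comparison": f"{m['class_a']} ({n_a}) vs {m['class_b']} ({n_b})",
                "n_per_class": {m["class_a"]: n_a, m["class_b"]: n_b},
                "orthogonal_components": m["n_orth"],
                "R2X": round(float(model.r2x), 6),
                "R2Y": round(float(model.r2y), 6),
                "significant_variables": sig_vars,
                "n_significant_variables": int(loadsig.significant.sum()),
                "stocsy": stocsy_block,
                "univariate": uni,
                "seeds": {"cv": seeds[0], "perm_model": seeds[1], "perm_loadings": seeds[2]},
            }
        )
        validations.append(
            {
                "Q2Y": round(float(cv.q2y), 6),
                "perm_p": round(float(perm.p_value), 6),
                "n_perm": perm.n_perm,
            }
        )
        log.info("model %s: Q2Y=%.3f perm_p=%.4g R2Y=%.3f R2X=%.3f",
                 m["name"], cv.q2y, perm.p_value, model.r2y, model.r2x)

    payload = sio.build_report(summaries, validations)
    payload["seed"] = config.seed
    if out is not None:
        import json

        (out / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    return payload
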