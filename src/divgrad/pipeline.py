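"""End-to-end orchestration: inputs -> diversity profiles -> inference tables.

``run`` reads (or simulates) a community matrix, trait table, phylogeny and
environment table, computes the plot x {TD, FD, PD} x q Hill-number
profile, then produces the three inference layers:

* pairwise attribute NB GLMs (overall and per region),
* NB GLMs of each attribute on signed latitude,
* NB GLMM candidate sets (all main-effect subsets of the four
  environmental predictors, region as random intercept) with AICc
  selection and Nakagawa R².

All outputs are tidy CSVs stamped with a hash of the run configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_model, phylo, stat_models
from .data_model import AlignedBundle, align_inputs
from .functional import hill_functional, trait_distance
from .phylo import branch_abundances, hill_phylo
from .simulate import SimulationConfig, simulate_study
from .taxonomic import hill_taxonomic

__all__ = ["RunConfig", "run", "report", "diversity_profile",
           "fit_glmm_candidates"]

PREDICTORS = ("temp_seasonality", "annual_precip", "soil_pH", "bulk_density")

OUTPUT_FILES = (
    "diversity_profile.csv", "attribute_glms.csv", "latitude_glms.csv",
    "glmm_candidates.csv", "glmm_selected.csv", "correlation_matrix.csv",
    "coverage_report.csv", "run.log",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to community/traits/tree/env files)
    or ``simulation`` (a SimulationConfig) must be given.
    """

    out_dir: str
    seed: int = 0
    inputs: dict | None = None
    simulation: SimulationConfig | None = None
    q_list: tuple = (0.0, 1.0, 2.0)
    distance_method: str = "gower"
    collinearity_threshold: float = 0.7
    n_quad: int = 15
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of 'inputs' and 'simulation' must be set")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and log
        verbosity excluded: they do not affect any computed value)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        for key in ("q_list",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


# ---------------------------------------------------------------------------
# diversity profile

def diversity_profile(
    cm, traits=None, tree=None, q_list: Sequence[float] = (0.0, 1.0, 2.0),
    distance_method: str = "gower", bundle: AlignedBundle | None = None,
) -> pd.DataFrame:
    """Hill-number profile per plot for every available attribute.

    TD is computed for every plot; FD on each plot's taxa with complete
    trait records (Rao-normalised functional Hill number qD(Q), the
    effective number of functional entities); PD on each plot's taxa with
    tree tips (total effective branch length, so q = 0 is Faith's PD).
    Plots with fewer than two usable taxa for FD/PD yield missing values.
    """
    if bundle is None:
        bundle = align_inputs(cm, traits, tree)
    rows = []
    for plot in cm.plots:
        entry = bundle.per_plot["TD"][plot]
        p = entry[1] if entry else None
        for q in q_list:
            rows.append({"plot": plot, "attribute": "TD", "q": q,
                         "value": hill_taxonomic(p, q) if p is not None
                         else np.nan})
    if "FD" in bundle.per_plot:
        fd_taxa = sorted({t for e in bundle.per_plot["FD"].values()
                          if e for t in e[0]})
        dmat = None
        if len(fd_taxa) >= 2:
            dmat = trait_distance(traits.subset(fd_taxa),
                                  method=distance_method)
        for plot in cm.plots:
            entry = bundle.per_plot["FD"][plot]
            for q in q_list:
                if entry is None or dmat is None:
                    val = np.nan
                else:
                    sub = dmat.subset(list(entry[0]))
                    val, _total = hill_functional(sub, entry[1], q)
                rows.append({"plot": plot, "attribute": "FD", "q": q,
                             "value": val})
    if "PD" in bundle.per_plot:
        for plot in cm.plots:
            entry = bundle.per_plot["PD"][plot]
            bas = None
            if entry is not None:
                bas = branch_abundances(tree, dict(zip(entry[0], entry[1])))
            for q in q_list:
                if bas is None:
                    val = np.nan
                else:
                    _mean, val = hill_phylo(bas, q)  # total effective length
                rows.append({"plot": plot, "attribute": "PD", "q": q,
                             "value": val})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLMM candidate fitting

def fit_glmm_candidates(
    y: pd.Series, env, n_quad: int = 15,
    predictors: Sequence[str] = PREDICTORS,
) -> list[stat_models.ModelFit]:
    """Fit the NB GLMM for every main-effect subset of ``predictors``.

    The region random intercept is always included; predictors are
    z-standardised.  Returns one ModelFit per subset (2^p candidates).
    """
    table = env.to_frame().loc[y.index]
    fits = []
    for r in range(len(predictors) + 1):
        for combo in itertools.combinations(predictors, r):
            X = stat_models.design_matrix(table, combo, standardize=True)
            formula = "y ~ (1|region)" + "".join(f" + {t}" for t in combo)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = stat_models.fit_nb_glmm(
                    y.to_numpy(), X, table["region"], n_quad=n_quad,
                    formula=formula,
                )
            fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# run

def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    cm = data_model.read_community(paths["community"])
    traits = data_model.read_traits(paths["traits"]) if "traits" in paths \
        else None
    tree = phylo.read_newick(paths["tree"]) if "tree" in paths else None
    env = data_model.read_env(paths["env"])
    return cm, traits, tree, env


def run(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    On a stage failure, outputs produced so far are retained and the
    exception is re-raised naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("divgrad.run")
    logger.setLevel(cfg.log_level)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    chash = cfg.config_hash()
    (out / "run_config.json").write_text(
        json.dumps(cfg.to_dict(), indent=1, default=str))

    def _write(df: pd.DataFrame, name: str):
        df = df.copy()
        df["config_hash"] = chash
        df.to_csv(out / name, index=False, float_format="%.10g")

    stage = "inputs"
    try:
        if cfg.simulation is not None:
            logger.info("simulating study inputs (seed=%s)",
                        cfg.simulation.seed)
            cm, traits, tree, env, truth = simulate_study(cfg.simulation)
            truth.to_json(out / "ground_truth.json")
            data_model.write_community(cm, out / "community.csv")
            data_model.write_traits(traits, out / "traits.csv")
            data_model.write_env(env, out / "env.csv")
            phylo.write_newick(tree, out / "tree.nwk")
        else:
            cm, traits, tree, env = _load_inputs(cfg)
        env.check_covers(cm)

        stage = "alignment"
        bundle = align_inputs(cm, traits, tree, env)
        _write(bundle.coverage, "coverage_report.csv")

        stage = "correlation screen"
        corr = stat_models.pearson_matrix(env, variables=[
            "latitude", *PREDICTORS])
        flagged = stat_models.flag_collinear(corr, cfg.collinearity_threshold)
        for a, b, r in flagged:
            logger.info("collinear pair |r|>=%.2f: %s ~ %s (r=%.3f)",
                        cfg.collinearity_threshold, a, b, r)
        corr_out = corr.reset_index().rename(columns={"index": "variable"})
        _write(corr_out, "correlation_matrix.csv")

        stage = "diversity profile"
        profiles = diversity_profile(
            cm, traits, tree, q_list=cfg.q_list,
            distance_method=cfg.distance_method, bundle=bundle)
        _write(profiles, "diversity_profile.csv")

        stage = "attribute cross GLMs"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cross = stat_models.attribute_cross_glms(profiles, env)
        _write(cross, "attribute_glms.csv")

        stage = "latitude GLMs"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat = stat_models.latitude_glms(profiles, env)
        _write(lat, "latitude_glms.csv")

        stage = "GLMM selection"
        wide = profiles.pivot_table(index="plot", columns=["attribute", "q"],
                                    values="value")
        cand_rows, sel_rows = [], []
        for attr, q in wide.columns:
            y = wide[(attr, q)].dropna()
            if len(y) < 10:
                logger.warning("skipping GLMM for %s q=%s (n=%d)",
                               attr, q, len(y))
                continue
            fits = fit_glmm_candidates(y, env, n_quad=cfg.n_quad)
            for f in fits:
                if not f.converged:
                    logger.warning("non-converged candidate %s (%s q=%s)",
                                   f.formula, attr, q)
                logger.info("%s q=%s %s lnL=%.3f AICc=%.3f", attr, q,
                            f.formula, f.llf, f.aicc)
            sel = stat_models.select_model(fits)
            ladder = sel.to_frame()
            ladder.insert(0, "attribute", attr)
            ladder.insert(1, "q", q)
            cand_rows.append(ladder)
            best = sel.selected
            X = stat_models.design_matrix(
                env.to_frame().loc[y.index],
                [t for t in PREDICTORS if t in best.params.index])
            rm2, rc2 = stat_models.nakagawa_r2(best, X)
            pvals = best.wald_p()
            sig_terms = [t for t in best.params.index
                         if t != "const" and pvals[t] < 0.05]
            sel_rows.append({
                "attribute": attr, "q": q, "formula": best.formula,
                "k": best.k, "AICc": best.aicc, "llf": best.llf,
                "theta": best.theta, "sigma_alpha": best.sigma_alpha,
                "Rm2": rm2, "Rc2": rc2,
                "significant_terms": ";".join(sig_terms),
            })
        _write(pd.concat(cand_rows, ignore_index=True), "glmm_candidates.csv")
        _write(pd.DataFrame(sel_rows), "glmm_selected.csv")
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# report

def report(out_dir) -> str:
    """Markdown summary of a completed run: pseudo-R² grids with
    significance stars and the AICc ladders with the selected model."""
    out = Path(out_dir)
    for name in ("attribute_glms.csv", "latitude_glms.csv",
                 "glmm_selected.csv", "glmm_candidates.csv"):
        if not (out / name).exists():
            raise FileNotFoundError(f"missing pipeline output: {out / name}")
    cross = pd.read_csv(out / "attribute_glms.csv")
    lat = pd.read_csv(out / "latitude_glms.csv")
    sel = pd.read_csv(out / "glmm_selected.csv")
    cand = pd.read_csv(out / "glmm_candidates.csv")
    for df in (cross, lat):
        df["stars"] = df["stars"].fillna("")

    lines = ["# Diversity-gradient run summary", ""]
    lines.append("## Attribute cross-model pseudo-R²")
    lines.append("")
    for pair in ("TD~FD", "TD~PD", "FD~PD"):
        block = cross[(cross["pair"] == pair) & (cross["scope"] == "all")]
        if block.empty or block["pR2"].isna().all():
            lines.append(f"- {pair}: not computed")
            continue
        cells = ", ".join(
            f"q={row.q:g}: {row.pR2:.2f}{row.stars}"
            for row in block.itertuples())
        lines.append(f"- {pair}: {cells}")
    lines.append("")
    lines.append("## Latitudinal trends (NB GLM on signed latitude)")
    lines.append("")
    for row in lat.itertuples():
        direction = "toward Equator" if row.slope_z > 0 else "away from Equator"
        lines.append(
            f"- {row.attribute} q={row.q:g}: pR²={row.pR2:.2f}{row.stars} "
            f"({direction})")
    lines.append("")
    lines.append("## Selected environmental GLMMs (AICc rule)")
    lines.append("")
    for row in sel.itertuples():
        ladder = cand[(cand["attribute"] == row.attribute)
                      & (cand["q"] == row.q)]
        lines.append(
            f"- {row.attribute} q={row.q:g}: **{row.formula}** "
            f"(AICc={row.AICc:.2f}, R²m={row.Rm2:.3f}, R²c={row.Rc2:.3f}; "
            f"{len(ladder)} candidates)")
    text = "\n".join(lines) + "\n"
    (out / "summary.md").write_text(text)
    return text
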