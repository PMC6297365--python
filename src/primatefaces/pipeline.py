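"""End-to-end orchestration: quantify -> morphometry -> agreement -> models.

A study run starts either from a synthetic configuration (everything is
generated in memory) or from user-supplied files (a directory of RGBA
stimuli, a TPS/CSV landmark file, rating CSVs, and a species metadata
table).  Stages always execute in the same order and write their
outputs into tidy tables; a provenance block (config hash, seed,
package version) accompanies every result set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imagequant import StimulusImage, color_profile, profiles_to_frame
from .morphometry import (
    cva,
    cva_loo_accuracy,
    fit_factors,
    label_facial_factors,
    load_landmarks,
    traits_frame,
)
from .raterstats import (
    RatingMatrix,
    gender_screen,
    icc_consistency,
    manova_wilks,
    spearman_brown,
)
from .models import (
    LinearModelFit,
    fit_lm,
    lowess_curve,
    rda_model_build,
    rda_permutation_terms,
    reduce_aic,
    tukey_hsd,
)
from .synthdata import make_study

__all__ = [
    "StudyConfig",
    "InputPaths",
    "StudyResults",
    "run_study",
    "run_models_stage",
    "validate_inputs",
    "export_report",
    "build_species_table",
]

#: Covariates entering the full attractiveness model, in sequential order.
FULL_MODEL_TERMS = [
    "group",
    "factor1",
    "factor2",
    "lg",
    "human_likeness",
    "mean_lightness",
    "pattern",
    "mean_saturation",
    "red_t",
    "orange_t",
    "yellow_t",
    "bluish_t",
]

GROUP_ORDER = ["catarrhine", "platyrrhine", "prosimian"]  # treatment reference first


@dataclass
class InputPaths:
    """File-based study inputs (the layout a data deposit is mapped onto)."""

    images_dir: str | Path
    landmarks: str | Path
    beauty_ratings: str | Path
    species_table: str | Path
    humanlikeness_ratings: str | Path | None = None


@dataclass
class StudyConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``synthetic`` (keyword arguments forwarded to
    :func:`primatefaces.synthdata.make_study`) and ``inputs`` must be
    provided.
    """

    synthetic: dict | None = None
    inputs: InputPaths | None = None
    seed: int = 0
    n_perm: int = 999
    alpha: float = 0.05
    edge_threshold: float = 0.1
    nose_convention: str = "as_printed"
    rda_response: str = "raters"  # "raters" | "gender_means"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'inputs' must be configured"
            )
        if self.rda_response not in ("raters", "gender_means"):
            raise ValueError("rda_response must be 'raters' or 'gender_means'")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")


@dataclass
class StudyResults:
    """All tables and fitted objects produced by one run."""

    species_table: pd.DataFrame
    color_profiles: pd.DataFrame
    traits: pd.DataFrame
    factor_loadings: pd.DataFrame
    factor_variance_explained: list[float]
    cva_eigenvalues: list[float]
    cva_scores: pd.DataFrame
    cva_accuracy: float
    agreement: dict
    gender_screen: pd.DataFrame
    manova: pd.DataFrame | None
    tukey: pd.DataFrame
    models: dict[str, LinearModelFit]
    rda_selected: list[str]
    rda_terms: pd.DataFrame
    rda_proportion_constrained: float
    rda_site_scores: pd.DataFrame
    rda_biplot_scores: pd.DataFrame
    lowess: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _config_hash(config: StudyConfig) -> str:
    def _default(o):
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, InputPaths):
            return asdict(o)
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_species_table(
    profiles: pd.DataFrame,
    factor_scores: pd.DataFrame,
    meta: pd.DataFrame,
    beauty: RatingMatrix,
    humanlikeness_means: pd.Series | None,
) -> pd.DataFrame:
    """Join per-species covariates and the mean attractiveness response.

    ``meta`` must carry ``group`` (and optionally ``genus_id``, ``lg``)
    per species.  The group column is made categorical with Catarrhini
    as the treatment-contrast reference level.
    """
    table = meta.copy()
    missing = set(table.index) ^ set(profiles.index)
    if missing:
        raise KeyError(f"species id mismatch between tables: {sorted(missing)[:5]}")
    table = table.join(profiles[["mean_lightness", "mean_saturation", "pattern",
                                 "red_t", "orange_t", "yellow_t", "bluish_t"]])
    table = table.join(factor_scores.rename(columns={"factor1": "factor1",
                                                     "factor2": "factor2"}))
    table["mean_beauty"] = beauty.species_means()
    if humanlikeness_means is not None:
        table["human_likeness"] = humanlikeness_means
    cats = [g for g in GROUP_ORDER if g in set(table["group"])]
    table["group"] = pd.Categorical(table["group"], categories=cats)
    return table


def run_models_stage(
    table: pd.DataFrame,
    beauty: RatingMatrix,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    rda_response: str = "raters",
) -> dict:
    """Fit the attractiveness models on a prepared species table.

    Runs the Tukey group comparison, the full + AIC-reduced linear
    models (all species pooled and per group), the RDA model building
    and sequential permutation tests, and the LOWESS attractiveness vs.
    human-likeness curve for the most human-like group.  Kept separate
    from :func:`run_study` so cached tables can be re-modelled.
    """
    table = table.copy()
    inverted_mean = 8.0 - table["mean_beauty"]
    tukey = tukey_hsd(inverted_mean.values, table["group"].astype(str).values)

    candidate_terms = [t for t in FULL_MODEL_TERMS if t == "group" or t in table]
    models: dict[str, LinearModelFit] = {}
    full = fit_lm(table, "mean_beauty", candidate_terms)
    models["all_primates"] = reduce_aic(full, alpha=alpha)
    for group in table["group"].cat.categories:
        sub = table[table["group"] == group]
        terms = [t for t in candidate_terms if t != "group"]
        if len(sub) > len(terms) + 2:
            gfit = fit_lm(sub, "mean_beauty", terms)
            models[str(group)] = reduce_aic(gfit, alpha=alpha)

    # RDA: response = species x raters score matrix (or gender means)
    if rda_response == "raters":
        Y = beauty.scores.T.loc[table.index]
    else:
        males = beauty.subset_gender("male").species_means()
        females = beauty.subset_gender("female").species_means()
        Y = pd.DataFrame({"male_mean": males, "female_mean": females}).loc[table.index]
    candidates: dict[str, np.ndarray] = {}
    for term in candidate_terms:
        if term == "group":
            candidates["group"] = pd.get_dummies(
                table["group"], drop_first=True
            ).values.astype(float)
        else:
            candidates[term] = table[term].values.astype(float)
    selected, rda_res, build_log = rda_model_build(
        Y, candidates, n_perm=n_perm, alpha=alpha, seed=seed
    )
    if selected:
        perm = rda_permutation_terms(
            Y, {k: candidates[k] for k in selected}, n_perm=n_perm, seed=seed + 1
        )
    else:
        perm = pd.DataFrame(columns=["f_value", "p_value", "n_perm"])

    # uncanny-valley curve within the most human-like group
    cat = table[table["group"] == "catarrhine"]
    if len(cat) >= 5 and "human_likeness" in cat:
        x = (8.0 - cat["human_likeness"]).values
        y = (8.0 - cat["mean_beauty"]).values
        fitted = lowess_curve(x, y)
        low = pd.DataFrame(
            {"human_likeness_inv": x, "mean_beauty_inv": y, "lowess": fitted},
            index=cat.index,
        ).sort_values("human_likeness_inv")
    else:
        low = pd.DataFrame(columns=["human_likeness_inv", "mean_beauty_inv", "lowess"])

    return {
        "tukey": tukey,
        "models": models,
        "rda_selected": selected,
        "rda_terms": perm,
        "rda_build_log": build_log,
        "rda_result": rda_res,
        "lowess": low,
    }


def run_study(config: StudyConfig) -> StudyResults:
    """Execute the full pipeline for one configuration."""
    config.validate()

    if config.synthetic is not None:
        synth_kwargs = dict(config.synthetic)
        synth_kwargs.setdefault("seed", config.seed)
        study = make_study(**synth_kwargs)
        images = study.images
        landmarks = study.landmarks
        beauty = study.beauty_ratings
        humanlike = study.humanlikeness_ratings
        meta = pd.DataFrame(
            {
                "species_id": [sp.species_id for sp in study.panel],
                "genus_id": [sp.genus_id for sp in study.panel],
                "group": [sp.group for sp in study.panel],
                "lg": [sp.lg_true for sp in study.panel],
            }
        ).set_index("species_id")
    else:
        paths = config.inputs
        report = validate_inputs(paths)
        errors = [r for r in report if r["severity"] == "error"]
        if errors:
            raise ValueError(
                "input validation failed: "
                + "; ".join(r["message"] for r in errors[:5])
            )
        images = {
            p.stem: StimulusImage.from_file(p)
            for p in sorted(Path(paths.images_dir).glob("*.png"))
            + sorted(Path(paths.images_dir).glob("*.tif"))
            + sorted(Path(paths.images_dir).glob("*.tiff"))
        }
        landmarks = load_landmarks(paths.landmarks)
        beauty = RatingMatrix.from_csv(paths.beauty_ratings)
        humanlike = (
            RatingMatrix.from_csv(paths.humanlikeness_ratings)
            if paths.humanlikeness_ratings
            else None
        )
        meta = pd.read_csv(paths.species_table).set_index("species_id")
        if "lg" not in meta and {"male_weight", "female_weight"}.issubset(meta.columns):
            from .models import lg_ratio

            meta["lg"] = [
                lg_ratio(m, f)
                for m, f in zip(meta["male_weight"], meta["female_weight"])
            ]

    # --- stage 1: color quantification -------------------------------------
    profiles = {
        sp_id: color_profile(img, edge_threshold=config.edge_threshold)
        for sp_id, img in images.items()
    }
    profiles_df = profiles_to_frame(profiles).rename(
        columns={f"{c}_t": f"{c}_t" for c in ("red", "orange", "yellow", "bluish")}
    )

    # --- stage 2: morphometry ----------------------------------------------
    traits = traits_frame(landmarks, nose_convention=config.nose_convention)
    traits = traits.loc[meta.index]
    fm = label_facial_factors(fit_factors(traits, n_factors=2))
    groups = meta["group"]
    from .morphometry import SingularScatterError

    try:
        cva_res = cva(traits, groups.values)
        loo = cva_loo_accuracy(traits, groups.values)
    except SingularScatterError:
        # small panels leave fewer within-group df than traits
        cva_res = cva(traits, groups.values, ridge=1e-8)
        loo = cva_loo_accuracy(traits, groups.values, ridge=1e-8)

    # --- stage 3: agreement ------------------------------------------------
    icc_pooled = icc_consistency(beauty)
    agreement = {
        "beauty_icc_single": icc_pooled.icc_single,
        "beauty_icc_average": icc_pooled.icc_average,
        "beauty_icc_average_sb": spearman_brown(
            icc_pooled.icc_single, beauty.n_raters
        ),
        "n_beauty_raters": beauty.n_raters,
    }
    for gender in ("male", "female"):
        try:
            sub = beauty.subset_gender(gender)
        except ValueError:
            continue
        r = icc_consistency(sub)
        agreement[f"beauty_icc_single_{gender}"] = r.icc_single
        agreement[f"beauty_icc_average_{gender}"] = r.icc_average
        agreement[f"n_{gender}_raters"] = sub.n_raters
    if humanlike is not None:
        r = icc_consistency(humanlike)
        agreement["humanlikeness_icc_single"] = r.icc_single
        agreement["humanlikeness_icc_average"] = r.icc_average
        agreement["n_humanlikeness_raters"] = humanlike.n_raters
    screen = gender_screen(beauty, alpha=config.alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            man = manova_wilks(
                beauty.scores,
                beauty.rater_meta,
                "age * gender",
            )
        except Exception as exc:  # degenerate demographic designs
            man = None
            agreement["manova_error"] = str(exc)

    # --- stage 4: species table + models -----------------------------------
    hl_means = humanlike.species_means() if humanlike is not None else None
    table = build_species_table(
        profiles_df, fm.scores, meta, beauty, hl_means
    )
    stage4 = run_models_stage(
        table,
        beauty,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=config.seed,
        rda_response=config.rda_response,
    )

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "n_species": int(len(table)),
        "mode": "synthetic" if config.synthetic is not None else "files",
    }
    return StudyResults(
        species_table=table,
        color_profiles=profiles_df,
        traits=traits,
        factor_loadings=fm.loadings,
        factor_variance_explained=[float(v) for v in fm.variance_explained],
        cva_eigenvalues=[float(v) for v in cva_res.eigenvalues],
        cva_scores=cva_res.scores,
        cva_accuracy=float(loo),
        agreement=agreement,
        gender_screen=screen,
        manova=man,
        tukey=stage4["tukey"],
        models=stage4["models"],
        rda_selected=stage4["rda_selected"],
        rda_terms=stage4["rda_terms"],
        rda_proportion_constrained=float(
            stage4["rda_result"].proportion_constrained
        ),
        rda_site_scores=stage4["rda_result"].site_scores,
        rda_biplot_scores=stage4["rda_result"].biplot_scores,
        lowess=stage4["lowess"],
        provenance=provenance,
    )


def validate_inputs(paths: InputPaths) -> list[dict]:
    """Check a file-based input bundle; returns a list of violations."""
    report: list[dict] = []

    def err(msg):
        report.append({"severity": "error", "message": msg})

    images_dir = Path(paths.images_dir)
    image_ids = set()
    if not images_dir.is_dir():
        err(f"images directory not found: {images_dir}")
    else:
        for p in sorted(images_dir.iterdir()):
            if p.suffix.lower() not in (".png", ".tif", ".tiff"):
                continue
            try:
                img = StimulusImage.from_file(p)
            except Exception as exc:
                err(f"unreadable image {p.name}: {exc}")
                continue
            image_ids.add(p.stem)
            if not (img.pixels[..., 3] < 0.5).any():
                report.append(
                    {"severity": "warning",
                     "message": f"image {p.name} has no transparent background"}
                )
            if not img.opaque_mask.any():
                err(f"image {p.name} has no opaque pixels")
        if not image_ids:
            err(f"no PNG/TIFF stimuli in {images_dir}")

    lm_ids = set()
    try:
        lms = load_landmarks(paths.landmarks)
        lm_ids = set(lms)
    except Exception as exc:
        err(f"landmark file: {exc}")

    rating_cols = set()
    for label, path in (
        ("beauty", paths.beauty_ratings),
        ("human-likeness", paths.humanlikeness_ratings),
    ):
        if path is None:
            continue
        try:
            m = RatingMatrix.from_csv(path)
            rating_cols |= set(m.stimulus_ids)
        except Exception as exc:
            err(f"{label} ratings: {exc}")

    try:
        meta = pd.read_csv(paths.species_table)
        if "species_id" not in meta.columns or "group" not in meta.columns:
            err("species table needs 'species_id' and 'group' columns")
        else:
            sp_ids = set(meta["species_id"].astype(str))
            for label, other in (
                ("images", image_ids),
                ("landmarks", lm_ids),
                ("ratings", rating_cols),
            ):
                if other and sp_ids - other:
                    err(
                        f"species missing from {label}: "
                        f"{sorted(sp_ids - other)[:5]}"
                    )
    except FileNotFoundError:
        err(f"species table not found: {paths.species_table}")
    return report


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), sig)
    return obj


def _model_block(fit: LinearModelFit) -> pd.DataFrame:
    """ANOVA + coefficient blocks for one model, in a report-table shape."""
    rows = []
    for term in fit.anova.index:
        if term == "Residual":
            continue
        rows.append(
            {
                "block": "anova", "term": term,
                "df": float(fit.anova.loc[term, "df"]),
                "F": float(fit.anova.loc[term, "F"]),
                "p": float(fit.anova.loc[term, "p"]),
            }
        )
    for name, row in fit.coefficients.iterrows():
        rows.append(
            {
                "block": "coefficients", "term": name,
                "estimate": float(row["estimate"]), "se": float(row["se"]),
                "t": float(row["t"]), "p": float(row["p"]),
            }
        )
    return pd.DataFrame(rows)


def export_report(results: StudyResults, outdir: str | Path,
                  format: str = "csv") -> list[Path]:
    """Write results as CSV tables and/or one JSON report; returns the paths."""
    if format not in ("csv", "json", "both"):
        raise ValueError("format must be 'csv', 'json', or 'both'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format in ("csv", "both"):
        tables = {
            "species_table.csv": results.species_table,
            "color_profiles.csv": results.color_profiles,
            "traits.csv": results.traits,
            "factor_loadings.csv": results.factor_loadings,
            "cva_scores.csv": results.cva_scores,
            "gender_screen.csv": results.gender_screen,
            "tukey.csv": results.tukey,
            "rda_terms.csv": results.rda_terms,
            "rda_site_scores.csv": results.rda_site_scores,
            "rda_biplot_scores.csv": results.rda_biplot_scores,
            "lowess.csv": results.lowess,
        }
        if results.manova is not None:
            tables["manova.csv"] = results.manova
        for name, fit in results.models.items():
            tables[f"model_{name}.csv"] = _model_block(fit)
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, float_format="%.6g")
            written.append(path)

    if format in ("json", "both"):
        payload = {
            "provenance": results.provenance,
            "agreement": results.agreement,
            "factor_variance_explained": results.factor_variance_explained,
            "cva_eigenvalues": results.cva_eigenvalues,
            "cva_loo_accuracy": results.cva_accuracy,
            "rda": {
                "selected_terms": results.rda_selected,
                "proportion_constrained": results.rda_proportion_constrained,
                "terms": results.rda_terms.reset_index().to_dict(orient="records"),
            },
            "models": {
                name: {
                    "formula": fit.formula,
                    "r_squared": fit.r_squared,
                    "aic": fit.aic,
                    "n": fit.n,
                    "terms": fit.terms,
                }
                for name, fit in results.models.items()
            },
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(_round_floats(payload), indent=2, sort_keys=True))
        written.append(path)
    return written
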