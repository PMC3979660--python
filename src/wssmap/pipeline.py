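"""End-to-end pipeline: simulate/load → fit → predict → inequality.

All randomness flows from one top-level seed, split deterministically per
stage and indicator, so a rerun with the same seed reproduces every output
byte-for-byte. Tabular outputs are CSV at 6 significant digits; posterior
draws are persisted at full precision as .npy arrays with a JSON manifest.
Outputs are written with a ``.partial`` suffix and renamed on success, so a
failed stage leaves its partial files identifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hierarchy import AdminHierarchy, PopulationTable
from .indicators import INDICATORS, read_sites_csv, write_sites_csv
from .inequality import (fit_gini_coverage_regression, gini_from_values,
                         lorenz_curve, rgi_scores, rgi_table)
from .model import CoverageModel, Hyperpriors, PosteriorDraws
from .predict import aggregate_population, coverage_table, national_table, predict_coverage
from .synthetic import (SimulationConfig, build_admin_hierarchy,
                        make_populations, sample_true_parameters,
                        simulate_survey)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_geojson"]

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ModelSettings:
    n_chains: int = 2
    n_iter: int = 2000
    n_warmup: int = 1000
    thin: int = 1
    hyperpriors: Hyperpriors = field(default_factory=Hyperpriors)
    t0: int = 2012


@dataclass
class PipelineConfig:
    """Pipeline configuration; exactly one of scenario / inputs is set."""

    output_dir: str
    seed: int = 0
    indicators: tuple[str, ...] = INDICATORS
    year: int = 2012
    scenario: SimulationConfig | None = None
    sites_path: str | None = None
    adjacency_path: str | None = None
    populations_path: str | None = None
    hierarchy_path: str | None = None
    boundaries_path: str | None = None
    model: ModelSettings = field(default_factory=ModelSettings)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        synthetic = self.scenario is not None
        real = self.sites_path is not None
        if synthetic == real:
            raise ValueError(
                "exactly one of a synthetic scenario or real input paths "
                "must be supplied"
            )
        unknown = set(self.indicators) - set(INDICATORS)
        if unknown:
            raise ValueError(f"unknown indicators: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            scenario = SimulationConfig(**scenario)
        inputs = raw.pop("inputs", {}) or {}
        model_raw = raw.pop("model", {}) or {}
        hyper = Hyperpriors(**(model_raw.pop("hyperpriors", {}) or {}))
        model = ModelSettings(hyperpriors=hyper, **model_raw)
        return cls(
            scenario=scenario,
            sites_path=inputs.get("sites"),
            adjacency_path=inputs.get("adjacency"),
            populations_path=inputs.get("populations"),
            hierarchy_path=inputs.get("hierarchy"),
            boundaries_path=inputs.get("boundaries"),
            model=model,
            indicators=tuple(raw.pop("indicators", INDICATORS)),
            **raw,
        )


def _stage_seed(seed: int, stage: str, index: int = 0) -> int:
    h = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _OutputWriter:
    """Writes files as <name>.partial, renaming them all on success."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: list[Path] = []
        outdir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        p = self.outdir / f"{name}.partial"
        self.pending.append(p)
        return p

    def write_csv(self, name: str, df: pd.DataFrame) -> None:
        df.to_csv(self.path(name), index=False, float_format="%.6g")

    def write_text(self, name: str, text: str) -> None:
        self.path(name).write_text(text)

    def finalize(self) -> list[Path]:
        final = []
        for p in self.pending:
            target = p.with_suffix("") if p.suffix == ".partial" else p
            target = p.parent / p.name[: -len(".partial")]
            p.rename(target)
            final.append(target)
        self.pending = []
        return final


def _load_inputs(config: PipelineConfig):
    """Load or simulate hierarchy, populations and site records."""
    if config.scenario is not None:
        scen = config.scenario
        hierarchy = build_admin_hierarchy(scen)
        populations = make_populations(
            hierarchy, _stage_seed(config.seed, "populations"))
        rng = np.random.default_rng(_stage_seed(config.seed, "truth"))
        truths = {
            ind: sample_true_parameters(hierarchy, rng, indicator=ind,
                                        t0=scen.t0)
            for ind in config.indicators
        }
        records = simulate_survey(
            hierarchy, populations, truths, scen,
            _stage_seed(config.seed, "survey"))
        return hierarchy, populations, records, truths

    for name, p in (("sites", config.sites_path),
                    ("adjacency", config.adjacency_path),
                    ("populations", config.populations_path)):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required {name} input missing: {p}")
    records = read_sites_csv(config.sites_path)
    adjacency = AdminHierarchy.read_adjacency(config.adjacency_path)
    if config.hierarchy_path:
        hdf = pd.read_csv(config.hierarchy_path)
        admin2_of = dict(zip(hdf["admin2"].astype(str), hdf["admin1"].astype(str)))
        admin1_of = dict(zip(hdf["admin1"].astype(str), hdf["country"].astype(str)))
        countries = sorted(set(admin1_of.values()))
    else:
        admin2_of = {r.admin2: r.admin1 for r in records if r.admin2 is not None}
        admin1_of = {r.admin1: r.country for r in records}
        countries = sorted({r.country for r in records})
    hierarchy = AdminHierarchy(countries=countries, admin1_of=admin1_of,
                               admin2_of=admin2_of, adjacency=adjacency)
    populations = PopulationTable.read_csv(config.populations_path)
    return hierarchy, populations, records, None


def country_gini_draws(
    overall: np.ndarray,
    admin2: list[str],
    country_of: list[str],
    populations: PopulationTable,
    complement: bool = False,
) -> dict[str, np.ndarray]:
    """Per-draw geographical GINI per country from overall-coverage draws."""
    carr = np.array(country_of)
    out: dict[str, np.ndarray] = {}
    for country in sorted(set(country_of)):
        mask = carr == country
        pops = np.array([populations.total(a)
                         for a, m in zip(admin2, mask) if m])
        keep = pops > 0
        draws = overall[:, mask][:, keep]
        if complement:
            draws = 1.0 - draws
        vals = np.empty(draws.shape[0])
        for i in range(draws.shape[0]):
            vals[i] = gini_from_values(draws[i], pops[keep])
        out[country] = vals
    return out


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] =
                 ("simulate", "fit", "predict", "inequality")) -> dict:
    """Run the requested stages; returns the output manifest.

    Stage failures raise :class:`PipelineError` naming the stage; files
    already produced by the failed run keep their ``.partial`` suffix.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.output_dir)
    writer = _OutputWriter(outdir)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "version": __version__,
        "python": sys.version.split()[0],
        "stages": list(stages),
        "inputs": {},
        "outputs": {},
    }

    try:
        hierarchy, populations, records, truths = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inputs", str(exc)) from exc
    for name in ("sites_path", "adjacency_path", "populations_path",
                 "hierarchy_path", "boundaries_path"):
        p = getattr(config, name)
        if p and Path(p).exists():
            manifest["inputs"][name] = _sha256(Path(p))

    if "simulate" in stages and config.scenario is not None:
        try:
            write_sites_csv(records, writer.path("sites.csv"))
            hierarchy.write_adjacency(writer.path("adjacency.txt"))
            populations.to_frame().to_csv(writer.path("populations.csv"),
                                          index=False)
            writer.write_csv("hierarchy.csv", hierarchy.to_frame())
            if truths:
                for ind, truth in truths.items():
                    truth.write_yaml(writer.path(f"truth_{ind}.yaml"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", str(exc)) from exc

    draws_by_indicator: dict[str, PosteriorDraws] = {}
    if "fit" in stages:
        for i, ind in enumerate(config.indicators):
            try:
                model = CoverageModel.from_records(
                    records, hierarchy, indicator=ind, t0=config.model.t0,
                    hyper=config.model.hyperpriors)
                res = model.fit(
                    n_chains=config.model.n_chains,
                    n_iter=config.model.n_iter,
                    n_warmup=config.model.n_warmup,
                    thin=config.model.thin,
                    seed=_stage_seed(config.seed, "fit", i))
                draws_by_indicator[ind] = res.draws
                res.draws.save(outdir / f"draws_{ind}")
                writer.write_text(f"diagnostics_{ind}.txt",
                                  str(res.diagnostics()))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("fit", f"indicator {ind}: {exc}") from exc

    if set(stages) & {"predict", "inequality"} and not draws_by_indicator:
        for ind in config.indicators:
            d = outdir / f"draws_{ind}"
            if not (d / "manifest.json").exists():
                raise PipelineError("predict",
                                    f"no posterior draws found at {d}")
            draws_by_indicator[ind] = PosteriorDraws.load(d)

    if "predict" in stages:
        boundaries = None
        if config.boundaries_path:
            boundaries = json.loads(Path(config.boundaries_path).read_text())
        all_tables = []
        for i, ind in enumerate(config.indicators):
            try:
                tab = coverage_table(
                    draws_by_indicator[ind], hierarchy, populations,
                    year=config.year, seed=_stage_seed(config.seed, "predict", i))
                nat = national_table(
                    draws_by_indicator[ind], hierarchy, populations,
                    year=config.year, seed=_stage_seed(config.seed, "predict", i))
                writer.write_csv(f"coverage_{ind}.csv", tab)
                writer.write_csv(f"national_{ind}.csv", nat)
                all_tables.append(tab)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("predict", f"indicator {ind}: {exc}") from exc
        if boundaries is not None:
            try:
                gj = write_geojson(pd.concat(all_tables), boundaries)
                writer.write_text("coverage.geojson", json.dumps(gj, indent=1))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("predict", f"geojson: {exc}") from exc

    if "inequality" in stages:
        ineq_rows = []
        lorenz_rows = []
        for i, ind in enumerate(config.indicators):
            try:
                seed_i = _stage_seed(config.seed, "predict", i)
                pred = predict_coverage(draws_by_indicator[ind], hierarchy,
                                        year=config.year, seed=seed_i)
                overall, national = aggregate_population(pred, populations)
                complement = ind == "open_defecation"
                gd = country_gini_draws(overall, pred.admin2, pred.country_of,
                                        populations, complement=complement)
                gini_pt = {c: float(np.median(v)) for c, v in gd.items()}
                cov_pt = {}
                for c in gd:
                    nat = np.nanmedian(national[c]["overall"])
                    cov_pt[c] = float(1.0 - nat) if complement else float(nat)
                if len(gd) >= 3:
                    reg = fit_gini_coverage_regression(gini_pt, cov_pt)
                    res = rgi_scores(gd, reg, indicator=ind)
                    ineq_rows.append(rgi_table(res))
                else:
                    logger.warning("fewer than 3 countries; RGI skipped for %s", ind)
                # point-estimate Lorenz curves for plotting
                carr = np.array(pred.country_of)
                med = np.nanmedian(overall, axis=0)
                if complement:
                    med = 1.0 - med
                for c in sorted(set(pred.country_of)):
                    mask = carr == c
                    pops = np.array([populations.total(a)
                                     for a, m in zip(pred.admin2, mask) if m])
                    keep = pops > 0
                    curve = lorenz_curve(med[mask][keep], pops[keep])
                    for q, L in zip(curve.q, curve.L):
                        lorenz_rows.append({"country": c, "indicator": ind,
                                            "q": q, "L": L})
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("inequality", f"indicator {ind}: {exc}") from exc
        if ineq_rows:
            writer.write_csv("inequality.csv", pd.concat(ineq_rows))
        writer.write_csv("lorenz.csv", pd.DataFrame(lorenz_rows))

    for path in writer.finalize():
        manifest["outputs"][path.name] = _sha256(path)
    for ind in draws_by_indicator:
        d = outdir / f"draws_{ind}" / "manifest.json"
        if d.exists():
            manifest["outputs"][f"draws_{ind}/manifest.json"] = _sha256(d)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest


def write_geojson(estimates: pd.DataFrame, boundaries: dict) -> dict:
    """Attach coverage estimates to a GeoJSON FeatureCollection.

    Features are matched on ``feature["id"]`` or
    ``feature["properties"]["admin2"]``; unmatched ids are listed in a
    warning and their features emitted without estimates. Properties added
    per indicator: ``<ind>_median/lower/upper/flag/basis`` (overall
    stratum).
    """
    if boundaries.get("type") != "FeatureCollection":
        raise ValueError("boundaries must be a GeoJSON FeatureCollection")
    est = estimates[estimates["stratum"] == "overall"]
    by_admin2: dict[str, pd.DataFrame] = dict(tuple(est.groupby("admin2")))
    out = {"type": "FeatureCollection", "features": []}
    unmatched = []
    for feature in boundaries.get("features", []):
        fid = feature.get("id") or feature.get("properties", {}).get("admin2")
        new = {"type": "Feature",
               "geometry": feature.get("geometry"),
               "properties": dict(feature.get("properties", {}))}
        if fid is not None:
            new["id"] = fid
        rows = by_admin2.get(fid)
        if rows is None:
            unmatched.append(fid)
        else:
            for _, row in rows.iterrows():
                ind = row["indicator"]
                new["properties"].update({
                    f"{ind}_median": round(float(row["median"]), 6),
                    f"{ind}_lower": round(float(row["lower"]), 6),
                    f"{ind}_upper": round(float(row["upper"]), 6),
                    f"{ind}_flag": row["flag"],
                    f"{ind}_basis": row["basis"],
                })
        out["features"].append(new)
    if unmatched:
        logger.warning("boundary features without estimates: %s", unmatched)
    missing_geo = set(by_admin2) - {
        f.get("id") or f.get("properties", {}).get("admin2")
        for f in boundaries.get("features", [])
    }
    if missing_geo:
        logger.warning("estimates without boundary features: %s",
                       sorted(missing_geo))
    return out
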