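"""End-to-end orchestration: simulate -> networks -> covariates -> screen ->
select model -> predict -> rank -> validate -> report.

Every stage writes plain-format outputs (CSV / GeoJSON / ESRI ASCII / YAML /
JSON) with a provenance header, so stages can be re-run standalone and a run
is reproducible from its ``config.yaml`` alone.  Identical config + seed
gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .cokriging import (
    CoKrigingPredictor,
    GridSpec,
    extract_at_waterbodies,
    predict_surface,
    water_mask_from_points,
)
from .covariates import assemble, inverse_road_distance, pearson_screen
from .errors import AisRiskError
from .modeling import KrigingSpec, auto_lag_size, build_data, fit_model
from .networks import (
    assign_streams,
    betweenness_centrality,
    build_traffic_network,
    connectivity_to_invaded,
    degree_centrality,
    eigenvector_centrality,
    select_centrality,
)
from .ranking import count_at_or_above, rank_by_quantiles, union_at_rank
from .synthetic import SPECIES, GeneratorConfig, Landscape, generate_landscape
from .validation import kfold_cv, select_model, true_validation

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "covariate_tables",
    "run_pipeline",
    "simulate_to_dir",
]

log = logging.getLogger("aisrisk")


class PipelineError(AisRiskError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    screening_threshold: float = 0.1
    lag_size: float | None = None  # None -> extent-scaled default
    n_lags: int = 12
    family: str = "spherical"
    anis_factor: float = 1.0
    anis_angle: float = 0.0
    max_points: int = 32
    search_radius_lags: float = 12.0
    zeros: str = "include"
    grid_cell: float | None = None  # None -> lag size
    n_classes: int = 5
    threshold_rank: int = 3
    kfold_k: int = 5
    seed: int = 0

    def kriging_spec(self, primary: str) -> KrigingSpec:
        return KrigingSpec(
            primary=primary,
            secondaries=(),
            lag_size=self.lag_size,
            n_lags=self.n_lags,
            family=self.family,
            anis_factor=self.anis_factor,
            anis_angle=self.anis_angle,
            max_points=self.max_points,
            search_radius_lags=self.search_radius_lags,
            zeros=self.zeros,
            zeros_seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if not isinstance(gen, GeneratorConfig):
            gen = GeneratorConfig(**gen)
        return cls(generator=gen, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self, seed=int(seed), generator=self.generator.with_seed(int(seed))
        )


def _setup_log(out: Path) -> None:
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def covariate_tables(
    land: Landscape, traffic: np.ndarray | None = None
) -> dict[str, pd.DataFrame]:
    """Assemble the six-variable covariate table for both census years.

    Stream assignment and connectivity use the reported (observed) invasion
    history — the analysis only ever sees reported data.  ``traffic``
    defaults to the landscape's eigenvector-centrality scores.
    """
    wb = land.waterbodies
    status = land.reported_status.set_index("id")
    if traffic is None:
        traffic = land.traffic_scores
    invaded_any = {
        wid for sp in SPECIES for wid in status.index[status[f"{sp}_t2"] > 0]
    }
    assignments = assign_streams(wb, land.streams, invaded_ids=invaded_any)
    road_scores = inverse_road_distance(wb, land.roads)
    tables = {}
    for yr in ("t1", "t2"):
        conn = {
            sp: connectivity_to_invaded(
                assignments, set(status.index[status[f"{sp}_{yr}"] > 0])
            )
            for sp in SPECIES
        }
        tables[yr] = assemble(
            wb, land.reported_status, conn, traffic, road_scores, yr
        )
    return tables


def simulate_to_dir(config: PipelineConfig, out: Path) -> Landscape:
    """Generate the landscape and write its layers."""
    land = generate_landscape(config.generator)
    prov = {"stage": "simulate", "seed": config.seed}
    wb = land.waterbodies.merge(
        land.reported_status.rename(
            columns={f"{sp}_{yr}": f"{sp}_{yr}" for sp in SPECIES for yr in ("t1", "t2")}
        ),
        on="id",
    )
    aio.write_table(wb, out / "waterbodies.csv", prov)
    aio.write_points_geojson(wb, out / "waterbodies.geojson")
    aio.write_lines_geojson(land.streams, out / "streams.geojson")
    aio.write_lines_geojson(land.roads, out / "roads.geojson", id_field=None)
    aio.write_table(land.surveys, out / "surveys.csv", prov)
    log.info(
        "simulate: %d waterbodies, %d streams, %d roads, %d surveys",
        len(wb), len(land.streams), len(land.roads), len(land.surveys),
    )
    return land


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns the summary dict written to summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_log(out)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    stage = "simulate"
    try:
        land = simulate_to_dir(config, out)
        wb = land.waterbodies
        status = land.reported_status.set_index("id")

        stage = "network"
        net = build_traffic_network(land.surveys, known_ids=set(wb["id"]))
        cents = {}
        if net.number_of_edges() > 0:
            cents = {
                "eigenvector": eigenvector_centrality(net),
                "betweenness": betweenness_centrality(net),
                "degree": degree_centrality(net),
            }
            status_by_sp = {
                sp: status[f"{sp}_t2"].astype(float) for sp in SPECIES
            }
            chosen_measure = select_centrality(cents, status_by_sp)
        else:
            chosen_measure = "eigenvector"
        traffic = (
            cents[chosen_measure].aligned(wb["id"]) if cents else np.zeros(len(wb))
        )
        cent_df = pd.DataFrame({"id": wb["id"]})
        for m, cv in cents.items():
            cent_df[m] = cv.aligned(wb["id"])
        aio.write_table(
            cent_df, out / "centrality.csv",
            {"stage": "network", "chosen_measure": chosen_measure,
             "n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges()},
        )
        log.info(
            "network: %d nodes, %d edges, chosen measure %s",
            net.number_of_nodes(), net.number_of_edges(), chosen_measure,
        )

        stage = "covariates"
        tables = covariate_tables(land, traffic)
        for yr in ("t1", "t2"):
            counts = {
                c: int((tables[yr][c] > 0).sum())
                for c in ("v1_zm", "v2_ewm", "v3_conn_zm", "v4_conn_ewm", "v5_eig")
            }
            aio.write_table(
                tables[yr], out / f"covariates_{yr}.csv",
                {"stage": "covariates", "year": yr, "counts": counts},
            )
            log.info("covariates %s: per-variable counts %s", yr, counts)

        stage = "screen"
        corr, candidates = pearson_screen(tables["t2"], config.screening_threshold)
        aio.write_table(
            corr.reset_index(names="variable"), out / "correlation.csv",
            {"stage": "screen", "threshold": config.screening_threshold},
        )
        (out / "candidates.json").write_text(json.dumps(candidates, indent=2))
        log.info("screen: candidates %s", candidates)

        summary: dict = {"seed": config.seed, "species": {}}
        rank_frames = []
        validation: dict = {}
        xy = wb[["x", "y"]].to_numpy(float)
        lag = config.lag_size if config.lag_size is not None else auto_lag_size(xy)
        cell = config.grid_cell if config.grid_cell is not None else lag
        grid = GridSpec.covering(xy, cell=cell)
        mask = water_mask_from_points(grid, xy)

        for sp, primary in (("zm", "v1_zm"), ("ewm", "v2_ewm")):
            stage = f"select-model[{sp}]"
            base = config.kriging_spec(primary)
            sel = select_model(
                tables["t1"], tables["t2"], candidates[primary], base,
                threshold_rank=config.threshold_rank,
            )
            spec = base.with_secondaries(sel.chosen)
            log.info(
                "%s: selected %s (AUC=%.3f) among %s",
                sp, sel.chosen, sel.chosen_auc,
                {"/".join(k): round(v, 3) for k, v in sel.evaluated.items()},
            )

            stage = f"fit[{sp}]"
            model = fit_model(tables["t2"], spec)
            aio.write_model_yaml(
                model, out / f"model_{sp}.yaml",
                {"stage": "fit", "species": sp, "secondaries": list(sel.chosen)},
            )

            stage = f"predict[{sp}]"
            predictor = CoKrigingPredictor(model, build_data(tables["t2"], spec))
            surface = predict_surface(predictor, grid, mask)
            aio.write_esri_ascii(surface, out / f"surface_{sp}.asc")
            probs = extract_at_waterbodies(surface, wb)

            stage = f"rank[{sp}]"
            ranking = rank_by_quantiles(wb["id"], probs, config.n_classes)
            rank_frames.append(
                ranking.to_frame().rename(
                    columns={"prob": f"prob_{sp}", "rank": f"rank_{sp}"}
                )
            )
            cnt, pct = count_at_or_above(ranking, config.threshold_rank)
            summary["species"][sp] = {
                "secondaries": list(sel.chosen),
                "selection_auc": sel.chosen_auc,
                "rank_counts": {
                    int(r): int((ranking.ranks == r).sum())
                    for r in range(1, config.n_classes + 1)
                },
                "at_or_above_threshold": {"count": cnt, "pct": pct},
            }

            stage = f"validate[{sp}]"
            tv = true_validation(
                tables["t1"], tables["t2"], spec, config.threshold_rank
            )
            cv = kfold_cv(
                tables["t2"], spec, k=config.kfold_k, seed=config.seed,
                threshold_rank=config.threshold_rank, model=model,
            )
            validation[sp] = {
                "true_validation": tv.to_dict(),
                "kfold": cv.to_dict(),
            }
            log.info(
                "%s: true-validation AUC=%.3f sens=%.2f spec=%.2f | "
                "kfold AUC=%.3f",
                sp, tv.auc, tv.sensitivity, tv.specificity, cv.auc,
            )
            summary["species"][sp]["rankings"] = ranking

        stage = "report"
        ranked = rank_frames[0].merge(rank_frames[1], on="id")
        aio.write_table(ranked, out / "ranked.csv", {"stage": "rank"})
        union = union_at_rank(
            summary["species"]["zm"].pop("rankings"),
            summary["species"]["ewm"].pop("rankings"),
            rank=config.n_classes,
        )
        summary["union_at_top_rank"] = union
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        (out / "validation.json").write_text(
            json.dumps(validation, indent=2, sort_keys=True)
        )
        log.info("report: union at top rank %s", union)
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"[{stage}] {exc}") from exc
    finally:
        for h in list(log.handlers):
            log.removeHandler(h)
            h.close()
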