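"""End-to-end orchestration: scene -> extent -> predictors -> map -> reports.

Thin glue over the stage modules so the analysis drivers, the tests and
the acceptance script all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify_validate as cv
from . import extent_mask as em
from . import predictors as pr
from . import synthetic_scene as ss
from .raster_core import RasterGrid


def compute_predictor_stack(bundle: ss.SceneBundle) -> pr.PredictorStack:
    """QA-screen the observations and compute all 11 predictor layers."""
    obs = pr.qa_screen(bundle.observations)
    years = bundle.config.years
    layers: dict[str, RasterGrid] = {}
    for kind in pr.INDEX_KINDS:
        idx_obs = [(o.date, pr.spectral_index(o, kind)) for o in obs]
        mean, cvar = pr.dry_season_stats(idx_obs, years)
        layers[f"{kind.lower()}_mean"] = mean
        layers[f"{kind.lower()}_cv"] = cvar
    layers["etap"] = pr.compute_etap(bundle.transp, bundle.precip, years)
    layers["cti"] = pr.compute_cti(bundle.dem)
    water = em.water_mask(bundle.landcover)
    layers["lst_anom"] = pr.compute_lst_anomaly(
        [(o.date, o.lst) for o in obs], water, years
    )
    return pr.assemble_predictors(layers)


@dataclass
class PipelineResult:
    """Everything one simulated mapping run produces."""

    bundle: ss.SceneBundle
    extent: em.ExtentMasks
    stack: pr.PredictorStack
    model: cv.TrainedModel
    test_report: cv.ValidationReport
    gde_map: cv.GDEMap
    dynamic_thr: float
    pixel_agreement: float
    gde_area_km2: float
    extras: dict = field(default_factory=dict)


def run_pipeline(
    config: ss.ScenarioConfig | None = None,
    n_gde: int = 1000,
    n_nongde: int = 1000,
    n_barren: int = 200,
    rf_config: cv.RFConfig = cv.PAPER_RF_CONFIG,
    threshold: float | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Simulate a scene and map it end to end.

    ``threshold=None`` selects the threshold dynamically on the held-out
    test points; pass 0.5 for the fixed 50% likelihood cut.  Pixelwise
    agreement compares the binary map with the planted truth over the
    analysis extent.
    """
    cfg = config if config is not None else ss.ScenarioConfig(seed=seed)
    bundle = ss.generate_scene(cfg)
    extent = ss.scene_extent(bundle)
    stack = compute_predictor_stack(bundle)

    points = ss.sample_points(bundle, n_gde, n_nongde, n_barren, seed=seed + 1)
    train, test = cv.split_train_test(points, seed=seed + 2)
    model = cv.train_rf(train, stack, rf_config)

    scores, kept = cv.score_points(model, stack, test)
    if threshold is None:
        thr = cv.dynamic_threshold(None, kept, scores=scores)
    else:
        thr = threshold
    predicted = np.where(scores >= thr, cv.GDE, cv.NONGDE)
    report = cv.confusion_metrics(predicted, kept["label"].to_numpy(),
                                  threshold=thr, context="test")

    prob = cv.predict_probability(model, stack, extent.extent)
    gde_map = cv.binarize(prob, thr)
    in_extent = extent.extent.values == 1.0
    mapped = gde_map.binary.values == cv.CODE_GDE
    truth = bundle.truth.values == 1.0
    agree = float(np.mean(mapped[in_extent] == truth[in_extent]))
    areas = gde_map.binary.cell_areas_km2()
    gde_area = float(np.sum(areas[in_extent & mapped]))

    return PipelineResult(
        bundle=bundle,
        extent=extent,
        stack=stack,
        model=model,
        test_report=report,
        gde_map=gde_map,
        dynamic_thr=thr,
        pixel_agreement=agree,
        gde_area_km2=gde_area,
    )
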