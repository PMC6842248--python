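"""End-to-end orchestration of the screen, morphology and titre analyses.

A single :class:`PipelineConfig` (YAML-loadable, CLI-overridable) carries the
input paths and the analysis parameters; defaults are the study conditions
(Spearman cutoff 0.5, enrichment FDR 0.05, dispersed/pellet area
thresholds 95/500 µm², t-test alpha 0.05, doxycycline doses 0/0.2/2/20
µg/ml). Every run writes a manifest recording the configuration and seeds so
outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import pandas as pd
import yaml

from mycoscreen import coexpression, enrichment, fermentation, morphology
from mycoscreen.synthetic import CONTROL_STRAIN, NEXUS_QUERY_GENES

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "DataError",
    "run_screen",
    "run_morphology",
    "run_titres",
    "run_all",
]

logger = logging.getLogger(__name__)


def _package_version() -> str:
    import mycoscreen

    return mycoscreen.__version__


class ConfigError(ValueError):
    """Invalid configuration (exit code 1 in the CLI)."""


class DataError(ValueError):
    """Invalid or missing input data (exit code 2 in the CLI)."""


@dataclass
class PipelineConfig:
    """All knobs of the three analyses; defaults are the study parameters."""

    out_dir: str = "results"
    # co-expression screen + enrichment
    matrix_path: str | None = None
    annotations_path: str | None = None
    query_genes: tuple[str, ...] = NEXUS_QUERY_GENES
    spearman_cutoff: float = 0.5
    q_threshold: float = 0.05
    # morphology
    image_dir: str | None = None
    manifest_path: str | None = None
    pixel_size_um: float = 1.0
    pellet_min_um2: float = morphology.PELLET_MIN_AREA_UM2
    dispersed_min_um2: float = morphology.DISPERSED_MIN_AREA_UM2
    # fermentation
    fermentation_path: str | None = None
    control_strain: str = CONTROL_STRAIN
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.query_genes = tuple(self.query_genes)
        if not 0 <= self.spearman_cutoff < 1:
            raise ConfigError("spearman_cutoff must lie in [0, 1)")
        if not 0 < self.q_threshold <= 1:
            raise ConfigError("q_threshold must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must lie in (0, 1]")
        for name in ("pixel_size_um", "pellet_min_um2", "dispersed_min_um2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.dispersed_min_um2 >= self.pellet_min_um2:
            raise ConfigError("dispersed threshold must lie below pellet threshold")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def write_manifest(self, out_dir: Path, stage: str) -> None:
        payload = dataclasses.asdict(self)
        payload["query_genes"] = list(self.query_genes)
        blob = json.dumps(payload, sort_keys=True).encode()
        manifest = {
            "stage": stage,
            "config": payload,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "package_version": _package_version(),
        }
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"manifest_{stage}.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )


def _out_dir(config: PipelineConfig) -> Path:
    path = Path(config.out_dir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def run_screen(config: PipelineConfig):
    """Multi-query co-expression screen plus GO enrichment of the intersection.

    Writes the intersection gene list, per-gene query support, the evaluated
    network edges (TSV + GraphML) and the enrichment report. Returns
    (ScreenResult, list of EnrichmentResult).
    """
    if config.matrix_path is None or config.annotations_path is None:
        raise ConfigError("screen requires matrix_path and annotations_path")
    try:
        matrix = coexpression.ExpressionMatrix.from_tsv(config.matrix_path)
    except FileNotFoundError as exc:
        raise DataError(str(exc)) from exc
    missing = [q for q in config.query_genes if q not in matrix.gene_ids]
    if missing:
        raise DataError(f"query genes absent from the matrix: {missing}")
    logger.info(
        "screen: %d genes x %d conditions, %d queries, cutoff %.2f",
        matrix.n_genes,
        matrix.n_conditions,
        len(config.query_genes),
        config.spearman_cutoff,
    )
    network = coexpression.build_network(
        matrix, cutoff=config.spearman_cutoff, query_restriction=config.query_genes
    )
    logger.info("screen: %d edges above cutoff", network.n_edges)
    result = coexpression.intersect_subnetworks(network, config.query_genes)
    logger.info("screen: intersection holds %d genes", result.intersection_size)

    out = _out_dir(config)
    (out / "intersection_genes.txt").write_text(
        "\n".join(sorted(result.intersection)) + "\n"
    )
    result.membership_table().to_csv(out / "screen_membership.csv", index=False)
    network.to_tsv(out / "network_edges.tsv")
    network.to_graphml(out / "network.graphml")

    annotations = enrichment.AnnotationSet.from_tsv(config.annotations_path)
    if result.intersection:
        results = enrichment.enrich(
            result.intersection, annotations, q_threshold=config.q_threshold
        )
        enrichment.results_table(results).to_csv(
            out / "enrichment_intersection.csv", index=False
        )
        n_reported = sum(r.reported for r in results)
        logger.info(
            "enrichment: %d terms tested, %d reported at q <= %.2f",
            len(results),
            n_reported,
            config.q_threshold,
        )
    else:
        results = []
        logger.warning("empty intersection; no enrichment computed")
    config.write_manifest(out, "screen")
    return result, results


def _load_manifest(config: PipelineConfig, files: list[Path]) -> pd.DataFrame:
    if config.manifest_path is None:
        return pd.DataFrame(
            {
                "file": [f.name for f in files],
                "strain": "unknown",
                "dox_ug_ml": float("nan"),
                "pixel_size_um": config.pixel_size_um,
            }
        )
    manifest = pd.read_csv(config.manifest_path)
    if "file" not in manifest.columns:
        raise DataError("image manifest needs a 'file' column")
    if "pixel_size_um" not in manifest.columns:
        manifest["pixel_size_um"] = config.pixel_size_um
    for col in ("strain", "dox_ug_ml"):
        if col not in manifest.columns:
            manifest[col] = "unknown" if col == "strain" else float("nan")
    names = {f.name for f in files}
    missing = sorted(set(manifest["file"]) - names)
    if missing:
        logger.warning("manifest lists missing image files (skipped): %s", missing)
        manifest = manifest[manifest["file"].isin(names)]
    return manifest


def run_morphology(config: PipelineConfig):
    """Quantify every image in the directory; returns (summary table, failures).

    Per image: per-structure metrics CSV plus one summary row (counts,
    pellet area fraction, MN statistics). Unreadable images are logged and
    skipped; their names are returned so callers can exit nonzero.
    """
    if config.image_dir is None:
        raise ConfigError("morphology requires image_dir")
    image_dir = Path(config.image_dir)
    files = sorted(
        p
        for p in image_dir.glob("*")
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not files:
        raise DataError(f"no PNG/TIFF images found in {image_dir}")
    manifest = _load_manifest(config, files)
    out = _out_dir(config)
    per_structure_dir = out / "structures"
    per_structure_dir.mkdir(exist_ok=True)

    rows = []
    failures = []
    by_name = {f.name: f for f in files}
    for entry in manifest.itertuples(index=False):
        path = by_name[entry.file]
        try:
            image = iio.imread(path)
            metrics = morphology.measure_structures(
                image, pixel_size_um=float(entry.pixel_size_um)
            )
        except Exception as exc:  # noqa: BLE001 - per-file error, run continues
            logger.error("failed to quantify %s: %s", path.name, exc)
            failures.append(path.name)
            continue
        morphology.metrics_table(metrics).to_csv(
            per_structure_dir / f"{path.stem}_structures.csv", index=False
        )
        summary = morphology.summarize_culture(metrics)
        rows.append(
            {
                "file": path.name,
                "strain": entry.strain,
                "dox_ug_ml": entry.dox_ug_ml,
                "n_pellets": summary.n_pellets,
                "n_dispersed": summary.n_dispersed,
                "n_excluded": summary.n_excluded,
                "pellet_area_fraction_pct": summary.pellet_area_fraction_pct,
                "mn_mean": summary.mn_mean,
                "mn_median": summary.mn_median,
            }
        )
        logger.info(
            "%s: %d pellets, %d dispersed, %.1f%% pellet area",
            path.name,
            summary.n_pellets,
            summary.n_dispersed,
            summary.pellet_area_fraction_pct,
        )
    summary_table = pd.DataFrame(rows)
    summary_table.to_csv(out / "morphology_summary.csv", index=False)
    if {"strain", "dox_ug_ml"} <= set(summary_table.columns) and len(summary_table):
        cohort = (
            summary_table.groupby(["strain", "dox_ug_ml"], dropna=False)
            .agg(
                n_images=("file", "size"),
                pellet_area_fraction_pct=("pellet_area_fraction_pct", "mean"),
                mn_mean=("mn_mean", "mean"),
            )
            .reset_index()
        )
        cohort.to_csv(out / "morphology_cohort.csv", index=False)
    config.write_manifest(out, "morphology")
    return summary_table, failures


def run_titres(config: PipelineConfig):
    """Normalise titres, test mutants against the control, fit trend curves.

    Returns (normalised table, comparison report, trend report). The trend
    fits mirror the published pairing: protein vs citric acid with a
    degree-2 polynomial, protein vs oxaloacetate with a linear fit, over
    strain x dose means.
    """
    if config.fermentation_path is None:
        raise ConfigError("titres requires fermentation_path")
    try:
        table = pd.read_csv(config.fermentation_path)
    except FileNotFoundError as exc:
        raise DataError(str(exc)) from exc
    try:
        normalized = fermentation.normalize_table(table)
        records = fermentation.records_from_frame(table)
        if config.control_strain not in set(table["strain"]):
            raise DataError(
                f"control strain {config.control_strain!r} absent from table"
            )
        comparisons = fermentation.compare_to_control(
            normalized, config.control_strain, alpha=config.alpha
        )
    except ValueError as exc:
        raise DataError(str(exc)) from exc

    means = fermentation.correlation_table(records)
    trend_rows = []
    for variable, degree in (
        ("citric_g_per_g_glucose", 2),
        ("oxaloacetate_g_per_g_glucose", 1),
    ):
        cells = means.dropna(subset=["protein_mg_per_g_biomass", variable])
        if len(cells) >= degree + 2 and cells[variable].nunique() > 1:
            fit = fermentation.fit_trend(
                cells[variable].to_numpy(),
                cells["protein_mg_per_g_biomass"].to_numpy(),
                degree=degree,
            )
            trend_rows.append(
                {
                    "pair": f"protein_vs_{variable}",
                    "degree": fit.degree,
                    "coefficients": json.dumps(list(fit.coefficients)),
                    "r_squared": fit.r_squared,
                }
            )
        else:
            logger.warning("too few strain x dose cells to fit %s", variable)
    trends = pd.DataFrame(
        trend_rows, columns=["pair", "degree", "coefficients", "r_squared"]
    )

    out = _out_dir(config)
    normalized.to_csv(out / "titres_normalized.csv", index=False)
    comparisons.to_csv(out / "titres_comparisons.csv", index=False)
    means.to_csv(out / "titres_means.csv", index=False)
    trends.to_csv(out / "titres_trends.csv", index=False)
    logger.info(
        "titres: %d comparisons (%d significant at alpha %.2f), %d trend fits",
        len(comparisons),
        int(comparisons["significant"].sum()) if len(comparisons) else 0,
        config.alpha,
        len(trends),
    )
    config.write_manifest(out, "titres")
    return normalized, comparisons, trends


def run_all(config: PipelineConfig) -> None:
    """Run every stage whose inputs are configured."""
    if config.matrix_path and config.annotations_path:
        run_screen(config)
    if config.image_dir:
        run_morphology(config)
    if config.fermentation_path:
        run_titres(config)
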