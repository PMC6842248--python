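"""Seeded synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the study's three data streams:

* an expression compendium (genes x cultivation conditions) with planted
  co-expression modules — noisy copies of a shared latent condition profile,
  so within-module Spearman correlation concentrates near a target value,
  against a background of independent-noise genes;
* binary culture images containing pellets (roughened ellipses) and dispersed
  fragments (small elongated blobs) with known ground-truth geometry;
* dose-response fermentation tables: per strain x doxycycline-dose model
  means for protein, dry weight, organic acids and depleted glucose, with
  multiplicative lognormal replicate noise.

All generators take explicit integer seeds and use no global random state;
the same (spec, seed) pair is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mycoscreen.coexpression import ExpressionMatrix
from mycoscreen.morphology import DISPERSED_MIN_AREA_UM2, PELLET_MIN_AREA_UM2

__all__ = [
    "ModuleSpec",
    "EllipseSpec",
    "FragmentSpec",
    "ImageSpec",
    "DoseResponseSpec",
    "generate_expression_matrix",
    "generate_go_annotations",
    "render_culture_image",
    "generate_fermentation_table",
    "nexus_screen_scenario",
    "NEXUS_QUERY_GENES",
    "NEXUS_REGULATOR_GENES",
    "NEXUS_PLANTED_TERMS",
    "example_dose_response_spec",
    "example_image_spec",
    "CONTROL_STRAIN",
]

# Query genes of the multi-gene screen: three TCA-cycle genes and three
# Golgi vesicle-coat (COPI/COPII) genes.
NEXUS_QUERY_GENES = ("citA", "idh2", "fumR", "copA", "sec13", "sec26")
# Arf-GTPase regulators expected to surface in the intersection.
NEXUS_REGULATOR_GENES = ("secG", "geaB", "ageB")
# GO terms planted on the nexus module: TCA cycle, Golgi-associated vesicle
# membrane, Golgi vesicle budding.
NEXUS_PLANTED_TERMS = ("GO:0006099", "GO:0030660", "GO:0048194")

CONTROL_STRAIN = "MA70.15"
DEFAULT_DOX_LEVELS = (0.0, 0.2, 2.0, 20.0)


# --------------------------------------------------------------------------
# expression compendium
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``latent_correlation`` is the target pairwise Spearman correlation among
    members; ``enriched_terms`` are GO terms planted on every member.
    """

    module_id: str
    member_genes: tuple[str, ...]
    latent_correlation: float
    enriched_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_genes", tuple(self.member_genes))
        object.__setattr__(self, "enriched_terms", tuple(self.enriched_terms))
        if not 0 < self.latent_correlation <= 1:
            raise ValueError("latent_correlation must lie in (0, 1]")
        if len(set(self.member_genes)) != len(self.member_genes):
            raise ValueError("duplicate member genes within a module")
        if not self.member_genes:
            raise ValueError("module needs at least one member gene")


def _latent_loading(latent_correlation: float, noise_sd: float) -> float:
    """Latent loading giving the target within-module Spearman correlation.

    Members are a * z + N(0, noise_sd²) on a shared standard-normal latent z,
    so pairwise Pearson correlation is a²/(a² + noise_sd²). For bivariate
    normals Spearman and Pearson are linked by
    rho_P = 2 sin(pi * rho_S / 6); inverting both gives the loading.
    """
    if noise_sd == 0 or latent_correlation == 1:
        return 1.0
    rho_p = 2.0 * math.sin(math.pi * latent_correlation / 6.0)
    return noise_sd * math.sqrt(rho_p / (1.0 - rho_p))


def generate_expression_matrix(
    n_genes: int,
    n_conditions: int,
    modules: Sequence[ModuleSpec],
    noise_sd: float,
    seed: int,
) -> ExpressionMatrix:
    """Expression matrix with planted modules over independent background genes.

    Gene universe = all module members (in module order) followed by
    background genes ``bg0001``… up to ``n_genes``. Module members are noisy
    monotone (linear) copies of a per-module latent profile; with
    ``noise_sd = 0`` members are exact copies and within-module Spearman is 1.
    """
    if n_conditions < 5:
        raise ValueError("need at least 5 conditions for a stable Spearman screen")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    member_lists = [set(m.member_genes) for m in modules]
    for i in range(len(member_lists)):
        for j in range(i + 1, len(member_lists)):
            overlap = member_lists[i] & member_lists[j]
            if overlap:
                raise ValueError(
                    f"modules {modules[i].module_id!r} and {modules[j].module_id!r} "
                    f"share genes: {sorted(overlap)[:5]}"
                )
    module_genes = [g for m in modules for g in m.member_genes]
    if len(module_genes) > n_genes:
        raise ValueError("module members exceed the requested gene universe")
    n_background = n_genes - len(module_genes)
    background = [f"bg{i + 1:04d}" for i in range(n_background)]
    clash = set(module_genes) & set(background)
    if clash:
        raise ValueError(f"module gene names collide with background names: {clash}")
    gene_ids = module_genes + background

    rng = np.random.default_rng(seed)
    values = np.empty((n_genes, n_conditions))
    row = 0
    for module in modules:
        latent = rng.standard_normal(n_conditions)
        loading = _latent_loading(module.latent_correlation, noise_sd)
        for _ in module.member_genes:
            noise = rng.standard_normal(n_conditions) * noise_sd
            values[row] = loading * latent + noise
            row += 1
    if n_background:
        values[row:] = rng.standard_normal((n_background, n_conditions))

    conditions = tuple(f"cond{i + 1:03d}" for i in range(n_conditions))
    return ExpressionMatrix(
        gene_ids=tuple(gene_ids), condition_ids=conditions, values=values
    )


def generate_go_annotations(
    gene_universe: Sequence[str],
    modules: Sequence[ModuleSpec],
    background_terms: int,
    terms_per_gene: int,
    seed: int,
) -> pd.DataFrame:
    """Two-column (gene, term) annotation table with planted module terms.

    Every module member carries its module's ``enriched_terms`` plus
    ``terms_per_gene`` random draws from a pool of ``background_terms``
    generic terms; background genes carry only random terms. With an empty
    background pool, genes without planted terms have nothing to carry and
    are omitted from the table (the annotation universe is the set of
    annotated genes).
    """
    if not gene_universe:
        raise ValueError("gene universe must be nonempty")
    if terms_per_gene < 1:
        raise ValueError("terms_per_gene must be at least 1")
    if background_terms < 0:
        raise ValueError("background_terms must be nonnegative")
    planted: dict[str, tuple[str, ...]] = {}
    for module in modules:
        for gene in module.member_genes:
            planted[gene] = module.enriched_terms
    unknown = set(planted) - set(gene_universe)
    if unknown:
        raise ValueError(f"module genes outside the universe: {sorted(unknown)[:5]}")

    pool = [f"BG:{i + 1:06d}" for i in range(background_terms)]
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    for gene in gene_universe:
        terms = set(planted.get(gene, ()))
        if pool:
            k = min(terms_per_gene, len(pool))
            terms.update(rng.choice(pool, size=k, replace=False).tolist())
        rows.extend((gene, term) for term in sorted(terms))
    return pd.DataFrame(rows, columns=["gene", "term"])


# --------------------------------------------------------------------------
# culture images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseSpec:
    """A pellet: an ellipse with optional sinusoidal boundary roughness.

    Axes are full diameters in µm; ``roughness`` perturbs the radius by the
    given fractional amplitude over ``lobes`` angular periods at constant
    target area pi * major * minor / 4.
    """

    center_um: tuple[float, float]  # (x, y) from the top-left image corner
    major_um: float
    minor_um: float
    orientation_deg: float = 0.0
    roughness: float = 0.0
    lobes: int = 7

    def __post_init__(self) -> None:
        if not self.major_um >= self.minor_um > 0:
            raise ValueError("require major >= minor > 0")
        if not 0 <= self.roughness < 0.5:
            raise ValueError("roughness amplitude must lie in [0, 0.5)")

    @property
    def area_um2(self) -> float:
        return math.pi * self.major_um * self.minor_um / 4.0


@dataclass(frozen=True)
class FragmentSpec:
    """A dispersed-mycelium fragment: a small oriented rectangular blob.

    ``elongation`` is length/width; target areas typically fall in the
    dispersed window [95, 500) µm².
    """

    center_um: tuple[float, float]
    area_um2: float
    elongation: float = 4.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("fragment area must be positive")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")


@dataclass(frozen=True)
class ImageSpec:
    """Layout of one synthetic binary culture image."""

    image_width_px: int
    image_height_px: int
    pixel_size_um: float
    pellet_specs: tuple[EllipseSpec, ...] = ()
    fragment_specs: tuple[FragmentSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pellet_specs", tuple(self.pellet_specs))
        object.__setattr__(self, "fragment_specs", tuple(self.fragment_specs))
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise ValueError("image dimensions must be positive")


def _ellipse_depth(
    spec: EllipseSpec, xs: np.ndarray, ys: np.ndarray, phase: float, scale: float
) -> np.ndarray:
    """Signed boundary depth of pixel centres (>= 0 inside the shape)."""
    theta = math.radians(spec.orientation_deg)
    dx = xs - spec.center_um[0]
    dy = ys - spec.center_um[1]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    a = spec.major_um / 2.0
    b = spec.minor_um / 2.0
    # normalised radial coordinate: 1 on the unperturbed boundary
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    if spec.roughness:
        ang = np.arctan2(v / b, u / a)
        boundary = 1.0 + spec.roughness * np.sin(spec.lobes * ang + phase)
    else:
        boundary = 1.0
    return boundary * scale - r


def _rect_depth(
    spec: FragmentSpec, xs: np.ndarray, ys: np.ndarray, scale: float
) -> np.ndarray:
    length = math.sqrt(spec.area_um2 * spec.elongation) * scale
    width = math.sqrt(spec.area_um2 / spec.elongation) * scale
    theta = math.radians(spec.orientation_deg)
    dx = xs - spec.center_um[0]
    dy = ys - spec.center_um[1]
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return np.minimum(length / 2.0 - np.abs(u), width / 2.0 - np.abs(v))


def _calibrated_mask(
    depth_fn, target_area_um2: float, pixel_area_um2: float
) -> np.ndarray:
    """Rasterise a shape so its pixel count matches the target area exactly.

    Bisection over a radial scale factor gets the count close; the residual
    (integer counts quantise the achievable area, and symmetric layouts make
    whole pixel rows enter at once) is corrected by trimming the shallowest
    boundary pixels or annexing the nearest outside pixels, ordered by the
    signed boundary depth. The rendered area then differs from the request
    only by the sub-pixel rounding of the target itself.
    """
    target_px = round(target_area_um2 / pixel_area_um2)
    if target_px < 1:
        raise ValueError("object smaller than one pixel at this resolution")

    def count(scale: float) -> int:
        return int((depth_fn(scale) >= 0).sum())

    lo, hi = 0.7, 1.4
    if count(lo) > target_px or count(hi) < target_px:
        raise ValueError("cannot calibrate object area within scale bounds")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_px:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda s: abs(count(s) - target_px))
    depth = depth_fn(best)
    mask = depth >= 0
    n = int(mask.sum())
    if n > target_px:  # trim the shallowest boundary pixels
        inside = np.argsort(depth[mask], kind="stable")[: n - target_px]
        rows, cols = np.nonzero(mask)
        mask[rows[inside], cols[inside]] = False
    elif n < target_px:  # annex the outside pixels nearest the boundary
        outside_depth = np.where(mask, -np.inf, depth)
        flat = np.argsort(outside_depth, axis=None, kind="stable")[::-1]
        add = flat[: target_px - n]
        mask.flat[add] = True
    return mask


def render_culture_image(spec: ImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterise an ImageSpec into a binary image plus a ground-truth table.

    Returns an 8-bit image (0 background, 255 foreground) and one row per
    object: requested geometry, true area, and the size class implied by the
    pellet/dispersed area thresholds. Objects must not overlap or touch the
    image border.
    """
    px = spec.pixel_size_um
    h, w = spec.image_height_px, spec.image_width_px
    rng = np.random.default_rng(spec.seed)

    canvas = np.zeros((h, w), dtype=bool)
    truth_rows = []
    object_id = 0

    def window(center_um, radius_um):
        """Pixel-centre coordinate grids cropped to the object's bounding box."""
        c0 = max(int((center_um[1] - radius_um) / px) - 1, 0)
        c1 = min(int((center_um[1] + radius_um) / px) + 2, h)
        r0 = max(int((center_um[0] - radius_um) / px) - 1, 0)
        r1 = min(int((center_um[0] + radius_um) / px) + 2, w)
        ys, xs = np.mgrid[c0:c1, r0:r1]
        return (c0, r0), (xs + 0.5) * px, (ys + 0.5) * px

    def place(local_mask: np.ndarray, origin: tuple[int, int], row: dict) -> None:
        nonlocal object_id
        if not local_mask.any():
            raise ValueError("object rasterised to zero pixels")
        mask = np.zeros((h, w), dtype=bool)
        mask[
            origin[0] : origin[0] + local_mask.shape[0],
            origin[1] : origin[1] + local_mask.shape[1],
        ] = local_mask
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError("object touches the image border")
        if (canvas & _dilate(mask)).any():
            raise ValueError("objects overlap or touch")
        object_id += 1
        canvas[mask] = True
        row["object_id"] = object_id
        truth_rows.append(row)

    max_scale = 1.4
    for pellet in spec.pellet_specs:
        phase = float(rng.uniform(0, 2 * math.pi))
        radius = pellet.major_um / 2.0 * (1.0 + pellet.roughness) * max_scale
        origin, xs_um, ys_um = window(pellet.center_um, radius)
        mask = _calibrated_mask(
            lambda s, p=pellet, ph=phase: _ellipse_depth(p, xs_um, ys_um, ph, s),
            pellet.area_um2,
            px**2,
        )
        place(
            mask,
            origin,
            {
                "true_area_um2": pellet.area_um2,
                "true_major_um": pellet.major_um,
                "true_minor_um": pellet.minor_um,
                "size_class": _true_class(pellet.area_um2),
            },
        )
    for frag in spec.fragment_specs:
        length = math.sqrt(frag.area_um2 * frag.elongation)
        width = math.sqrt(frag.area_um2 / frag.elongation)
        radius = math.hypot(length, width) / 2.0 * max_scale
        origin, xs_um, ys_um = window(frag.center_um, radius)
        mask = _calibrated_mask(
            lambda s, f=frag: _rect_depth(f, xs_um, ys_um, s),
            frag.area_um2,
            px**2,
        )
        place(
            mask,
            origin,
            {
                "true_area_um2": frag.area_um2,
                "true_major_um": length,
                "true_minor_um": width,
                "size_class": _true_class(frag.area_um2),
            },
        )

    image = np.where(canvas, 255, 0).astype(np.uint8)
    truth = pd.DataFrame(
        truth_rows,
        columns=["object_id", "true_area_um2", "true_major_um", "true_minor_um", "size_class"],
    )
    return image, truth


def _true_class(area_um2: float) -> str:
    if area_um2 >= PELLET_MIN_AREA_UM2:
        return "pellet"
    if area_um2 >= DISPERSED_MIN_AREA_UM2:
        return "dispersed"
    return "excluded"


def _dilate(mask: np.ndarray) -> np.ndarray:
    """One-pixel 8-connected dilation, so placed objects never touch."""
    out = mask.copy()
    out[:-1, :] |= mask[1:, :]
    out[1:, :] |= mask[:-1, :]
    out[:, :-1] |= mask[:, 1:]
    out[:, 1:] |= mask[:, :-1]
    out[:-1, :-1] |= mask[1:, 1:]
    out[1:, 1:] |= mask[:-1, :-1]
    out[:-1, 1:] |= mask[1:, :-1]
    out[1:, :-1] |= mask[:-1, 1:]
    return out


# --------------------------------------------------------------------------
# fermentation tables
# --------------------------------------------------------------------------

_MEASUREMENT_KEYS = (
    "protein_mg",
    "dry_weight_g",
    "citric_g_l",
    "oxaloacetate_g_l",
    "glucose_depleted_g_l",
)


@dataclass(frozen=True)
class DoseResponseSpec:
    """Strain x dose model means plus replicate noise for a shake-flask table.

    ``effect_model[strain][dose]`` maps each measurement column to its model
    mean. Replicates are the mean times a lognormal multiplier with unit mean
    and coefficient of variation ``noise_cv``.
    """

    strains: tuple[str, ...]
    effect_model: Mapping[str, Mapping[float, Mapping[str, float]]]
    dox_levels: tuple[float, ...] = DEFAULT_DOX_LEVELS
    replicate_count: int = 4
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        object.__setattr__(self, "dox_levels", tuple(self.dox_levels))
        if self.replicate_count < 2:
            raise ValueError("replicate_count must be at least 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        for strain in self.strains:
            if strain not in self.effect_model:
                raise ValueError(f"no effect model for strain {strain!r}")
            for dose, means in self.effect_model[strain].items():
                for key in _MEASUREMENT_KEYS:
                    if key not in means:
                        raise ValueError(
                            f"effect model for {strain!r} at dose {dose} missing {key!r}"
                        )
                    if means[key] < 0:
                        raise ValueError("model means must be nonnegative")


def generate_fermentation_table(spec: DoseResponseSpec) -> pd.DataFrame:
    """Shake-flask measurement table: replicate rows per strain x dose.

    Doses absent from a strain's effect model are skipped (0 µg/ml
    doxycycline is typically omitted for strains whose target gene is
    essential, since they cannot grow uninduced). With
    ``noise_cv = 0`` every replicate equals the model mean exactly.
    """
    cv = spec.noise_cv
    if cv > 0:
        sigma2 = math.log1p(cv**2)
        mu = -sigma2 / 2.0  # unit-mean lognormal multiplier
        sigma = math.sqrt(sigma2)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for strain in spec.strains:
        for dose in spec.dox_levels:
            if dose not in spec.effect_model[strain]:
                continue
            means = spec.effect_model[strain][dose]
            for rep in range(1, spec.replicate_count + 1):
                row = {"strain": strain, "dox_ug_ml": dose, "replicate": rep}
                for key in _MEASUREMENT_KEYS:
                    mean = means[key]
                    if cv > 0 and mean > 0:
                        mult = float(rng.lognormal(mean=mu, sigma=sigma))
                    else:
                        mult = 1.0
                    row[key] = mean * mult
                rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["strain", "dox_ug_ml", "replicate", *_MEASUREMENT_KEYS],
    )


# --------------------------------------------------------------------------
# study-condition scenarios
# --------------------------------------------------------------------------


def nexus_screen_scenario(
    seed: int,
    n_background_genes: int = 1000,
    n_conditions: int = 155,
    module_size: int = 50,
    latent_correlation: float = 0.9,
    noise_sd: float = 0.3,
    background_terms: int = 150,
    terms_per_gene: int = 5,
) -> tuple[ExpressionMatrix, pd.DataFrame, ModuleSpec, tuple[str, ...]]:
    """Compendium + annotations with one planted nexus module.

    The module holds the six query genes (TCA: citA, idh2, fumR; Golgi:
    copA, sec13, sec26), the three Arf regulators (secG, geaB, ageB) and
    filler members up to ``module_size``, all tracking one latent condition
    profile at the target Spearman correlation; 155 conditions matches the
    compendium's count of distinct cultivation conditions and the background
    gene count keeps the screen's false-positive behaviour measurable.

    Returns (matrix, annotation table, module spec, query genes).
    """
    n_filler = module_size - len(NEXUS_QUERY_GENES) - len(NEXUS_REGULATOR_GENES)
    if n_filler < 0:
        raise ValueError("module_size too small for queries plus regulators")
    members = (
        NEXUS_QUERY_GENES
        + NEXUS_REGULATOR_GENES
        + tuple(f"nx{i + 1:03d}" for i in range(n_filler))
    )
    module = ModuleSpec(
        module_id="nexus",
        member_genes=members,
        latent_correlation=latent_correlation,
        enriched_terms=NEXUS_PLANTED_TERMS,
    )
    matrix = generate_expression_matrix(
        n_genes=module_size + n_background_genes,
        n_conditions=n_conditions,
        modules=[module],
        noise_sd=noise_sd,
        seed=seed,
    )
    annotations = generate_go_annotations(
        gene_universe=list(matrix.gene_ids),
        modules=[module],
        background_terms=background_terms,
        terms_per_gene=terms_per_gene,
        seed=seed + 1,
    )
    return matrix, annotations, module, NEXUS_QUERY_GENES


def _flat_model(protein, dry_weight, citric, oxalo, glucose):
    return {
        "protein_mg": protein,
        "dry_weight_g": dry_weight,
        "citric_g_l": citric,
        "oxaloacetate_g_l": oxalo,
        "glucose_depleted_g_l": glucose,
    }


def example_dose_response_spec(seed: int = 0, noise_cv: float = 0.1) -> DoseResponseSpec:
    """Dose-response effect model with the strains' qualitative pattern.

    Progenitor control MA70.15 is dose-independent. The secG conditional
    strain (TC4.4) secretes no citric acid at 0 and 0.2 µg/ml Dox, less than
    the control at 20 µg/ml, accumulates oxaloacetate at low dose, and shows
    slightly elevated protein without Dox. The essential-gene strains TC5.5
    (ageB) and TC6.1 (geaB) lack the 0 µg/ml condition, secrete drastically
    less protein at 0.2 µg/ml, recover at 2 µg/ml, and TC5.5 drops again at
    20 µg/ml. Magnitudes are order-of-scale choices for a shake-flask run
    (tens of mg protein, grams-per-litre acids), not reconstructions of the
    unpublished measurements.
    """
    control = _flat_model(120.0, 1.5, 9.0, 0.15, 45.0)
    model = {
        CONTROL_STRAIN: {d: control for d in DEFAULT_DOX_LEVELS},
        "TC4.4": {  # secG
            0.0: _flat_model(140.0, 1.4, 0.0, 0.6, 40.0),
            0.2: _flat_model(125.0, 1.45, 0.0, 0.55, 42.0),
            2.0: _flat_model(120.0, 1.5, 8.0, 0.2, 44.0),
            20.0: _flat_model(118.0, 1.5, 5.5, 0.18, 45.0),
        },
        "TC5.5": {  # ageB, essential: no 0 µg/ml condition
            0.2: _flat_model(25.0, 0.8, 2.0, 0.1, 20.0),
            2.0: _flat_model(115.0, 1.45, 8.5, 0.15, 44.0),
            20.0: _flat_model(90.0, 1.4, 7.5, 0.14, 43.0),
        },
        "TC6.1": {  # geaB, essential: no 0 µg/ml condition
            0.2: _flat_model(22.0, 0.75, 1.8, 0.09, 19.0),
            2.0: _flat_model(118.0, 1.5, 8.8, 0.15, 44.0),
            20.0: _flat_model(116.0, 1.5, 8.6, 0.15, 45.0),
        },
    }
    return DoseResponseSpec(
        strains=tuple(model),
        effect_model=model,
        dox_levels=DEFAULT_DOX_LEVELS,
        replicate_count=4,
        noise_cv=noise_cv,
        seed=seed,
    )


def example_image_spec(
    seed: int = 0,
    pixel_size_um: float = 2.0,
    n_pellets: int = 6,
    n_fragments: int = 8,
    image_px: int = 1200,
) -> ImageSpec:
    """A culture-image layout with pellets and dispersed fragments on a grid.

    Pellet diameters span roughly 100–600 µm (areas well above 500 µm²) with
    mild boundary roughness; fragment areas span the dispersed window
    [95, 500) µm². Objects are laid out on a jittered grid so they never
    overlap.
    """
    rng = np.random.default_rng(seed)
    n_objects = n_pellets + n_fragments
    side = math.ceil(math.sqrt(n_objects))
    extent_um = image_px * pixel_size_um
    cell = extent_um / side
    centers = []
    for i in range(side):
        for j in range(side):
            cx = (j + 0.5) * cell + float(rng.uniform(-0.05, 0.05)) * cell
            cy = (i + 0.5) * cell + float(rng.uniform(-0.05, 0.05)) * cell
            centers.append((cx, cy))
    order = rng.permutation(len(centers))[:n_objects]

    pellets = []
    for k in range(n_pellets):
        major = float(rng.uniform(150.0, min(500.0, cell * 0.55)))
        minor = major * float(rng.uniform(0.6, 1.0))
        pellets.append(
            EllipseSpec(
                center_um=centers[order[k]],
                major_um=major,
                minor_um=minor,
                orientation_deg=float(rng.uniform(0, 180)),
                roughness=float(rng.uniform(0.0, 0.12)),
                lobes=int(rng.integers(5, 10)),
            )
        )
    fragments = []
    for k in range(n_fragments):
        fragments.append(
            FragmentSpec(
                center_um=centers[order[n_pellets + k]],
                area_um2=float(rng.uniform(100.0, 480.0)),
                elongation=float(rng.uniform(1.5, 8.0)),
                orientation_deg=float(rng.uniform(0, 180)),
            )
        )
    return ImageSpec(
        image_width_px=image_px,
        image_height_px=image_px,
        pixel_size_um=pixel_size_um,
        pellet_specs=tuple(pellets),
        fragment_specs=tuple(fragments),
        seed=seed,
    )
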