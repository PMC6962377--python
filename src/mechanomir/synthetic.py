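"""Synthetic inputs with known ground truth for every pipeline stage.

The raw inputs of the original study -- fluorescence wound-assay images, a
transcriptome-array differential-expression table, and per-miRNA pathway
database exports -- are not publicly deposited, so this module generates
statistically matched stand-ins: wound image pairs with exactly known
cell-free areas, aspect-ratio samples drawn from the condition presets,
expression tables with a known differentially expressed subset, and a
pathway/target database whose group labels and overlaps are known by
construction.  Two small fixture tables transcribe the published selected
mRNA panel and the 27 differentially regulated precursor miRNAs.

All randomness flows through explicit integer seeds (default 42).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interaction import PATHWAY_GROUPS, classify_pathway
from .presets import ConditionPreset, get_preset

__all__ = [
    "DEFAULT_SEED",
    "SyntheticWoundPair",
    "SyntheticExpressionSet",
    "SyntheticPathwayDB",
    "generate_ar_sample",
    "generate_wound_pair",
    "generate_expression_set",
    "generate_pathway_db",
    "load_mrna_panel",
    "load_mirna_panel",
    "mirna_relevance_annotation",
]

DEFAULT_SEED = 42

#: Image geometry for synthetic wound pairs: 1000 x 1000 px at 1.61 um/px
#: (4x-objective class); the gap is a vertical band.
DEFAULT_IMAGE_SHAPE = (1000, 1000)
DEFAULT_PIXEL_SIZE = 1.61  # um per px

EXPRESSION_COLUMNS = ["feature_id", "feature_type", "fold_change", "p_value", "fdr"]


@dataclass(frozen=True)
class SyntheticWoundPair:
    """An initial/final image pair with segmentation-free truth areas (px^2)."""

    image_initial: np.ndarray
    image_final: np.ndarray
    true_area_initial: int
    true_area_final: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.image_initial.shape != self.image_final.shape:
            raise ValueError("image pair must share a shape")
        if not 0 <= self.true_area_final <= self.true_area_initial:
            raise ValueError("final area must be in [0, initial area]")


@dataclass(frozen=True)
class SyntheticExpressionSet:
    """Expression table plus the ids generated as differentially expressed."""

    records: pd.DataFrame
    truth_de_ids: frozenset[str]

    def __post_init__(self) -> None:
        ids = self.records["feature_id"]
        if ids.duplicated().any():
            raise ValueError("feature ids must be unique")
        missing = self.truth_de_ids - set(ids)
        if missing:
            raise ValueError(f"truth DE ids absent from records: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class SyntheticPathwayDB:
    """Long-format export table plus pathway -> group truth labels."""

    exports: pd.DataFrame
    truth_groups: dict[str, str] = field(hash=False)


def _resolve_preset(preset: ConditionPreset | str) -> ConditionPreset:
    return preset if isinstance(preset, ConditionPreset) else get_preset(preset)


def generate_ar_sample(
    preset: ConditionPreset | str, n: int, seed: int = DEFAULT_SEED
) -> np.ndarray:
    """Draw n aspect ratios from a preset's shifted-lognormal mixture.

    Each draw picks a component by the mixture weights and returns
    1 + lognormal(mu, sigma), so every value exceeds 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = _resolve_preset(preset)
    rng = np.random.default_rng(seed)
    mix = p.mixture
    comp = rng.choice(mix.n_components, size=n, p=list(mix.weights))
    mus = np.asarray(mix.mus)[comp]
    sigmas = np.asarray(mix.sigmas)[comp]
    return 1.0 + rng.lognormal(mean=mus, sigma=sigmas)


def generate_wound_pair(
    gap_width: float = 500.0,
    closure: float = 0.57,
    texture_seed: int = DEFAULT_SEED,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> SyntheticWoundPair:
    """Build an initial/final wound-assay image pair at a known closure.

    The initial image carries a dark vertical cell-free band ``gap_width``
    micrometres wide on a bright speckled cell texture; the final image's
    band is narrowed symmetrically so its area is (1 - closure) times the
    initial area, exact up to one-pixel rounding.  Images are 16-bit
    grayscale.
    """
    if not 0.0 <= closure <= 1.0:
        raise ValueError(f"closure must lie in [0, 1], got {closure}")
    if gap_width <= 0:
        raise ValueError("gap_width must be positive (um)")
    h, w = image_shape
    gap_px = int(round(gap_width / pixel_size))
    if gap_px >= w:
        raise ValueError("gap wider than the image")
    final_px = int(round(gap_px * (1.0 - closure)))

    rng = np.random.default_rng(texture_seed)

    def _render(band_px: int) -> tuple[np.ndarray, int]:
        img = rng.normal(0.55, 0.12, size=(h, w))
        # sparse bright nuclei-like speckle on the cell lawn
        n_speck = (h * w) // 400
        ys = rng.integers(0, h, n_speck)
        xs = rng.integers(0, w, n_speck)
        img[ys, xs] += rng.uniform(0.2, 0.45, n_speck)
        if band_px > 0:
            lo = (w - band_px) // 2
            img[:, lo : lo + band_px] = rng.normal(0.06, 0.02, size=(h, band_px))
        img = np.clip(img, 0.0, 1.0)
        return (img * 65535).astype(np.uint16), band_px * h

    image_initial, area_initial = _render(gap_px)
    image_final, area_final = _render(final_px)
    return SyntheticWoundPair(
        image_initial=image_initial,
        image_final=image_final,
        true_area_initial=area_initial,
        true_area_final=area_final,
        pixel_size=pixel_size,
    )


def generate_expression_set(
    n_features: int,
    n_de: int,
    fc_range: tuple[float, float] = (2.5, 8.0),
    seed: int = DEFAULT_SEED,
    mirna_fraction: float = 0.15,
) -> SyntheticExpressionSet:
    """Emulate a differential-expression table with a known DE subset.

    Exactly ``n_de`` features pass the triple filter (p < 0.05, FDR < 0.05,
    |FC| > 2): their |FC| is uniform in ``fc_range`` with random sign and
    their FDR is below 0.05.  The remaining features fail on |FC|, on FDR,
    or on p.  FDR values are assigned directly (the upstream empirical-Bayes
    testing is consumed, not recomputed, by this pipeline).  Feature types
    are precursor_mirna with probability ``mirna_fraction``, else coding.
    """
    if n_de > n_features:
        raise ValueError("n_de must not exceed n_features")
    if fc_range[0] <= 2.0:
        raise ValueError("fc_range lower bound must exceed 2 (the filter cut)")
    rng = np.random.default_rng(seed)
    ids = np.array([f"GENE{i:05d}" for i in range(n_features)])
    types = np.where(
        rng.random(n_features) < mirna_fraction, "precursor_mirna", "coding"
    )
    fc = np.empty(n_features)
    p = np.empty(n_features)
    fdr = np.empty(n_features)

    de_idx = rng.choice(n_features, size=n_de, replace=False)
    is_de = np.zeros(n_features, dtype=bool)
    is_de[de_idx] = True

    # DE rows: big FC, significant p and FDR
    sign = rng.choice([-1.0, 1.0], size=n_de)
    fc[de_idx] = sign * rng.uniform(*fc_range, size=n_de)
    fdr[de_idx] = rng.uniform(1e-4, 0.049, size=n_de)
    p[de_idx] = fdr[de_idx] * rng.uniform(0.2, 1.0, size=n_de)

    # null rows fail exactly one of the three gates (possibly more)
    null_idx = np.flatnonzero(~is_de)
    mode = rng.integers(0, 3, size=null_idx.size)
    for j, i in zip(mode, null_idx):
        s = rng.choice([-1.0, 1.0])
        if j == 0:  # small effect
            fc[i] = s * rng.uniform(1.0, 1.99)
            fdr[i] = rng.uniform(1e-4, 0.9)
            p[i] = fdr[i] * rng.uniform(0.2, 1.0)
        elif j == 1:  # big effect, not FDR-significant
            fc[i] = s * rng.uniform(1.0, fc_range[1])
            fdr[i] = rng.uniform(0.05, 0.95)
            p[i] = fdr[i] * rng.uniform(0.2, 1.0)
        else:  # not even nominally significant
            fc[i] = s * rng.uniform(1.0, fc_range[1])
            p[i] = rng.uniform(0.05, 0.95)
            fdr[i] = min(1.0, p[i] * rng.uniform(1.0, 2.0))

    records = pd.DataFrame(
        {
            "feature_id": ids,
            "feature_type": types,
            "fold_change": np.round(fc, 4),
            "p_value": p,
            "fdr": fdr,
        }
    )
    return SyntheticExpressionSet(
        records=records, truth_de_ids=frozenset(ids[is_de])
    )


# One name template per functional group; each contains a keyword the default
# classifier maps to that group and nothing that matches a higher-priority
# rule. Round-tripping is asserted at generation time.
_GROUP_NAME_TEMPLATES = {
    "Cancer": "glioma progression module {i}",
    "Motility": "cell projection morphogenesis {i}",
    "DNA Repair": "dna repair complex assembly {i}",
    "Cell Cycle": "cell cycle checkpoint control {i}",
    "Apoptosis": "apoptotic process regulation {i}",
    "Miscellaneous": "metabolite transmembrane transport {i}",
    "Canonical": "mapk signaling cascade {i}",
}

_SOURCE_DATABASES = ("KEGG", "GO-BP", "WikiPathways", "Reactome")


def generate_pathway_db(
    n_pathways_per_group: int,
    mirnas: list[str],
    targets_per_pathway: int,
    seed: int = DEFAULT_SEED,
    gene_pool: list[str] | None = None,
    pathways_per_mirna: int | None = None,
    groups: tuple[str, ...] = PATHWAY_GROUPS,
) -> SyntheticPathwayDB:
    """Emulate per-miRNA pathway-database exports with known group truth.

    A pool of ``n_pathways_per_group x len(groups)`` pathways is built from
    per-group name templates, so the keyword classifier recovers every truth
    group exactly.  Each miRNA's export contains ``pathways_per_mirna``
    pathways (default: the whole pool), each with a source-database label,
    an enrichment p < 0.05, and a target set drawn from ``gene_pool``
    (default: a synthetic gene universe of 500 ids).
    """
    if n_pathways_per_group < 1 or targets_per_pathway < 1:
        raise ValueError("counts must be >= 1")
    if not mirnas:
        raise ValueError("need at least one miRNA")
    rng = np.random.default_rng(seed)
    if gene_pool is None:
        gene_pool = [f"GENE{i:05d}" for i in range(500)]
    if targets_per_pathway > len(gene_pool):
        raise ValueError("targets_per_pathway exceeds the gene pool")

    truth_groups: dict[str, str] = {}
    pool: list[str] = []
    for g in groups:
        template = _GROUP_NAME_TEMPLATES[g]
        for i in range(1, n_pathways_per_group + 1):
            name = template.format(i=i)
            assigned = classify_pathway(name)
            if assigned != g:  # template/classifier drift guard
                raise RuntimeError(
                    f"generated name {name!r} classifies to {assigned}, wanted {g}"
                )
            truth_groups[name] = g
            pool.append(name)

    k = pathways_per_mirna if pathways_per_mirna is not None else len(pool)
    if not 1 <= k <= len(pool):
        raise ValueError("pathways_per_mirna out of range")

    rows = []
    genes = np.asarray(gene_pool)
    for m in mirnas:
        chosen = rng.choice(len(pool), size=k, replace=False)
        for ci in sorted(chosen):
            targets = rng.choice(genes, size=targets_per_pathway, replace=False)
            rows.append(
                {
                    "mirna": m,
                    "pathway": pool[ci],
                    "database": _SOURCE_DATABASES[
                        int(rng.integers(len(_SOURCE_DATABASES)))
                    ],
                    "enrichment_p": float(rng.uniform(1e-4, 0.049)),
                    "targets": frozenset(targets.tolist()),
                }
            )
    return SyntheticPathwayDB(exports=pd.DataFrame(rows), truth_groups=truth_groups)


def _load_fixture(name: str) -> pd.DataFrame:
    path = importlib.resources.files("mechanomir") / "data" / name
    with importlib.resources.as_file(path) as f:
        return pd.read_csv(f, sep="\t")


def load_mrna_panel() -> pd.DataFrame:
    """Transcription of the published selected-mRNA panel (9 coding genes).

    Fold changes and FDR are as printed; the raw p column is a synthetic
    placeholder set equal to the FDR (an upper bound on the unpublished raw
    p, and below 0.05 for every row).
    """
    return _load_fixture("de_mrna_panel.tsv")


def load_mirna_panel() -> pd.DataFrame:
    """Transcription of the 27 differentially regulated precursor miRNAs.

    Fold changes are as printed; p and FDR are synthetic placeholders (0.01)
    since only fold change was published for this table -- all rows passed
    the study's triple filter by construction.  ``gbm_relevant`` preserves
    the published two-class split (11 literature-substantiated vs 16 not).
    """
    return _load_fixture("de_precursor_mirna.tsv")


def mirna_relevance_annotation() -> dict[str, str]:
    """Two-class GBM-relevance annotation keyed by reported miRNA id."""
    panel = load_mirna_panel()
    return {
        row.feature_id: ("gbm_relevant" if row.gbm_relevant else "unsubstantiated")
        for row in panel.itertuples(index=False)
    }
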