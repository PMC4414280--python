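"""End-to-end orchestration: specimens -> feature sets -> DAPC -> exports.

A run takes either the synthetic cohort generator or a manifest of wing
scans with TPS landmark files, produces the three coefficient sets
(landmark 200, chromaticity 63, Gabor 510) plus their combination, fits a
DAPC per feature set, writes contribution and Mahalanobis tables with the
per-pair summary, builds the continuous character matrix, and records a
machine-readable, deterministic run log.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .charmatrix import build_matrix, export_matrix
from .chromaticity import chromaticity_vector, region_catalogue
from .discriminant import (
    FeatureMatrix,
    contribution_vectors,
    dapc_fit,
    loo_assignment_accuracy,
    mahalanobis_matrix,
    md_summary,
    top_contributors,
)
from .gabor import bank_catalogue, build_bank, gwt_vector
from .imaging import SquareImage, segment_wing, square_compose, to_grayscale
from .landmarks import LandmarkSet, assemble_vector, mean_shape, procrustes_align
from .synthetic import SyntheticSpecimen, generate_cohort, make_wingform_library
from .tps import read_tps

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "extract_features",
    "specimens_from_manifest",
    "run_pipeline",
]

FEATURE_SETS = ("LM", "CHRM", "GWT", "ALL")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, specimen: str, message: str):
        super().__init__(f"stage {stage!r}, specimen {specimen!r}: {message}")
        self.stage = stage
        self.specimen = specimen


@dataclass
class PipelineConfig:
    """Validated description of one pipeline run."""

    input: str = "synthetic"  # "synthetic" or path to a manifest CSV
    out_dir: str = "wingquant_run"
    seed: int = 0
    n_per_form: int = 10
    length_px: int = 512
    n_pcs: int = 50
    md_threshold: float = 3.0
    feature_sets: tuple[str, ...] = FEATURE_SETS
    char_matrix_forms: tuple[str, ...] | None = None  # None = male forms only
    export_dialects: tuple[str, ...] = ("tnt", "nexus")

    def validate(self) -> None:
        if self.input != "synthetic" and not Path(self.input).exists():
            raise ValueError(f"manifest {self.input!r} does not exist")
        if self.n_per_form < 1 or self.length_px < 64 or self.n_pcs < 1:
            raise ValueError("n_per_form, length_px and n_pcs must be positive")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets {sorted(unknown)}")


def specimens_from_manifest(manifest_path: str | Path):
    """Load real specimens: scans plus TPS landmarks.

    The manifest CSV needs columns ``specimen_id``, ``wingform``,
    ``fore_image``, ``hind_image``, ``fore_tps``, ``hind_tps`` (paths
    relative to the manifest).  TPS records are matched to specimens by
    their ``ID=`` field.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    base = manifest_path.parent
    required = {"specimen_id", "wingform", "fore_image", "hind_image", "fore_tps", "hind_tps"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    tps_cache: dict[str, dict[str, np.ndarray]] = {}

    def lms(tps_file: str, specimen_id: str) -> np.ndarray:
        if tps_file not in tps_cache:
            tps_cache[tps_file] = {
                r.id: r.coords for r in read_tps(base / tps_file)
            }
        try:
            return tps_cache[tps_file][specimen_id]
        except KeyError:
            raise PipelineError("landmarks", specimen_id, f"no TPS record in {tps_file}")

    specimens = []
    for _, row in table.iterrows():
        sid = str(row["specimen_id"])
        specimens.append(
            SyntheticSpecimen(
                specimen_id=sid,
                wingform=str(row["wingform"]),
                fore_image=np.asarray(iio.imread(base / row["fore_image"]), dtype=float) / 255.0,
                hind_image=np.asarray(iio.imread(base / row["hind_image"]), dtype=float) / 255.0,
                truth_fore_lms=lms(row["fore_tps"], sid),
                truth_hind_lms=lms(row["hind_tps"], sid),
                truth_fore_mask=None,
                truth_hind_mask=None,
                seed=-1,
            )
        )
    labels = table[["specimen_id", "wingform"]].copy()
    return specimens, labels


def _landmark_catalogue() -> pd.DataFrame:
    rows = []
    for wing in ("fore", "hind"):
        for lm in range(1, 51):
            for axis in ("x", "y"):
                rows.append({"wing": wing, "landmark": lm, "axis": axis})
    return pd.DataFrame(rows)


def extract_features(
    specimens: list[SyntheticSpecimen], n_pcs: int = 50
) -> dict:
    """Run imaging + three coefficient extractions over a cohort.

    Returns feature DataFrames (indexed by specimen id), the per-set
    FeatureMatrix objects, the composed squares, aligned landmark sets and
    any warnings collected along the way.
    """
    labels = [s.wingform for s in specimens]
    ids = [s.specimen_id for s in specimens]
    squares: list[SquareImage] = []
    warnings_log: list[str] = []
    fore_sets: list[LandmarkSet] = []
    hind_sets: list[LandmarkSet] = []
    bank = build_bank()
    chrm_rows, gwt_rows = [], []

    for s in specimens:
        try:
            fmask = segment_wing(s.fore_image)
            hmask = segment_wing(s.hind_image)
        except Exception as e:  # noqa: BLE001 - stage failure carries specimen id
            raise PipelineError("segmentation", s.specimen_id, str(e)) from e
        try:
            sq = square_compose(
                s.fore_image, fmask, s.hind_image, hmask, specimen_id=s.specimen_id
            )
        except Exception as e:
            raise PipelineError("squaring", s.specimen_id, str(e)) from e
        squares.append(sq)
        cv = chromaticity_vector(sq, specimen_id=s.specimen_id, label=s.wingform)
        if cv.degenerate:
            warnings_log.append(
                f"{s.specimen_id}: degenerate chromaticity regions {cv.degenerate}"
            )
        chrm_rows.append(cv.values)
        gwt_rows.append(gwt_vector(to_grayscale(sq), bank).values)
        fore_sets.append(LandmarkSet(coords=s.truth_fore_lms, wing="fore"))
        hind_sets.append(LandmarkSet(coords=s.truth_hind_lms, wing="hind"))

    fore_aligned = procrustes_align(fore_sets, wing="fore")
    hind_aligned = procrustes_align(hind_sets, wing="hind")
    lm_rows = [
        assemble_vector(f, h, specimen_id=i, label=l).values
        for f, h, i, l in zip(fore_aligned, hind_aligned, ids, labels)
    ]

    chrm_cols = [f"{r}_{c}" for r in region_catalogue() for c in ("r", "g", "b")]
    gwt_cols = [
        f"s{d['scale']}_r{d['row']}c{d['col']}_rot{int(d['rotation'])}_{d['component']}"
        for d in bank_catalogue(bank)
    ]
    lm_cols = [
        f"{w}_lm{lm}_{ax}"
        for w in ("fore", "hind")
        for lm in range(1, 51)
        for ax in ("x", "y")
    ]
    frames = {
        "LM": pd.DataFrame(lm_rows, index=ids, columns=lm_cols),
        "CHRM": pd.DataFrame(chrm_rows, index=ids, columns=chrm_cols),
        "GWT": pd.DataFrame(gwt_rows, index=ids, columns=gwt_cols),
    }
    frames["ALL"] = pd.concat([frames["LM"], frames["CHRM"], frames["GWT"]], axis=1)

    catalogues = {
        "LM": _landmark_catalogue(),
        "CHRM": pd.DataFrame(
            [{"region": r, "channel": c} for r in region_catalogue() for c in ("r", "g", "b")]
        ),
        "GWT": pd.DataFrame(bank_catalogue(bank)),
    }
    catalogues["ALL"] = pd.concat(
        [cat.assign(source=src) for src, cat in list(catalogues.items())[:3]],
        ignore_index=True,
    )
    matrices = {
        name: FeatureMatrix(
            X=frames[name].to_numpy(),
            labels=labels,
            specimen_ids=ids,
            name=name,
            catalogue=catalogues[name],
        )
        for name in frames
    }
    return {
        "frames": frames,
        "matrices": matrices,
        "squares": squares,
        "fore_aligned": fore_aligned,
        "hind_aligned": hind_aligned,
        "labels": labels,
        "specimen_ids": ids,
        "warnings": warnings_log,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write all artifacts to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input == "synthetic":
        library = make_wingform_library()
        specimens, label_table = generate_cohort(
            library, config.n_per_form, seed=config.seed, length_px=config.length_px
        )
    else:
        specimens, label_table = specimens_from_manifest(config.input)

    feats = extract_features(specimens, n_pcs=config.n_pcs)
    label_table.to_csv(out / "labels.csv", index=False)

    md_tables: dict[str, pd.DataFrame] = {}
    for name in config.feature_sets:
        frame = feats["frames"][name]
        frame.to_csv(out / f"features_{name}.csv")
        result = dapc_fit(feats["matrices"][name], n_pcs=config.n_pcs)
        pd.DataFrame(
            result.ld_scores,
            index=feats["specimen_ids"],
            columns=[f"LD{j + 1}" for j in range(result.n_axes)],
        ).assign(wingform=feats["labels"]).to_csv(out / f"dapc_{name}_scores.csv")
        contrib = contribution_vectors(result)
        pd.DataFrame(
            contrib, index=frame.columns,
            columns=[f"LD{j + 1}" for j in range(contrib.shape[1])],
        ).to_csv(out / f"contributions_{name}.csv")
        top_contributors(result).to_csv(out / f"top_contributors_{name}.csv", index=False)
        md = mahalanobis_matrix(result)
        md.to_csv(out / f"md_{name}.csv")
        md_tables[name] = md

    summary = md_summary(md_tables, threshold=config.md_threshold)
    summary.to_csv(out / "md_summary.csv", index=False)

    # per-wingform mean shapes (Procrustes space)
    shape_rows = []
    for wing, aligned in (("fore", feats["fore_aligned"]), ("hind", feats["hind_aligned"])):
        for lab, ms in mean_shape(aligned, feats["labels"]).items():
            for lm, (x, y) in enumerate(ms.coords, start=1):
                shape_rows.append(
                    {"wingform": lab, "wing": wing, "landmark": lm, "x": x, "y": y}
                )
    pd.DataFrame(shape_rows).to_csv(out / "mean_shapes.csv", index=False)

    # character matrix over male wingforms (or a configured subset)
    forms = config.char_matrix_forms
    if forms is None:
        forms = tuple(f for f in sorted(set(feats["labels"])) if not f.endswith("F"))
    keep = [i for i, l in enumerate(feats["labels"]) if l in forms]
    if keep:
        take = lambda name: feats["frames"][name].iloc[keep]  # noqa: E731
        cm = build_matrix(take("LM"), take("CHRM"), take("GWT"))
        for dialect in config.export_dialects:
            ext = "tnt" if dialect == "tnt" else "nex"
            export_matrix(cm, out / f"charmatrix.{ext}", dialect=dialect)
        cm.provenance.to_csv(out / "charmatrix_provenance.csv", index=False)
        retained, dropped = cm.n_characters, len(cm.dropped)
    else:
        retained = dropped = 0

    config_log = asdict(config)
    config_log.pop("out_dir")  # path-independent so reruns are byte-identical
    log = {
        "wingquant_version": __version__,
        "python": sys.version.split()[0],
        "config": config_log,
        "n_specimens": len(specimens),
        "wingforms": sorted(set(feats["labels"])),
        "characters_retained": retained,
        "characters_dropped": dropped,
        "warnings": feats["warnings"],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
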