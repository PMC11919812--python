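"""End-to-end orchestration: read -> match -> features -> classify -> QC.

The per-structure flow mirrors the detector's five stages: template scan,
reduction to the closest template per site, rASA computation, logistic
classification, and (optionally, for sites called positive) geometric
quality control.  Structures that fail to parse are logged and skipped;
the run only fails when every input fails.
"""
from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

from . import classifier as clf
from . import geometry as geo
from .features import SiteFeatures, compute_rasa, compute_sasa
from .matcher import MatchHit, SearchConfig, exclude_by_identity, find_matches, reduce_to_best
from .structure_io import (
    Structure,
    StructureError,
    TSV_COLUMNS,
    read_structure,
    write_tsv,
)
from .templates import TemplateLibrary, load_library

logger = logging.getLogger("isopeptide_detect")


@dataclasses.dataclass
class RunConfig:
    inputs: list[Path]
    template_dir: Path | None = None
    model_path: Path | None = None
    geometry_ref_path: Path | None = None
    search: SearchConfig = dataclasses.field(default_factory=SearchConfig)
    threshold: float | None = None     # None: use the model's stored threshold
    sasa_points: int = 500
    qc_enabled: bool = True
    evaluation_mode: bool = False      # apply the 30% flank-identity exclusion
    output: Path | None = None

    def __post_init__(self) -> None:
        if self.threshold is not None and not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclasses.dataclass
class SiteResult:
    structure_id: str
    hit: MatchHit
    features: SiteFeatures
    prediction: clf.Prediction
    geometry: geo.GeometryReport | None = None

    def to_row(self) -> dict:
        lys, cat, acc = self.hit.site
        row = {col: None for col in TSV_COLUMNS}
        row.update(
            structure_id=self.structure_id,
            chain=lys.chain_id,
            r1_bond=lys.seq_id,
            r_cat=cat.seq_id,
            r2_bond=acc.seq_id,
            r1_bond_name=lys.res_name,
            r_cat_name=cat.res_name,
            r2_bond_name=acc.res_name,
            probability=self.prediction.probability,
            rmsd=self.hit.rmsd,
            r_asa=self.features.r_asa,
            template=self.hit.template_id,
            type=self.hit.topology,
        )
        if self.geometry is not None:
            g = self.geometry
            row.update(
                bond_length=g.bond_length,
                zscore=g.zscore,
                zscore_flag="outlier" if g.zscore_outlier else "ok",
                phi_psi_likelihood=g.pair_likelihoods[("phi", "psi")],
                omega_psi_likelihood=g.pair_likelihoods[("omega", "psi")],
                omega_phi_likelihood=g.pair_likelihoods[("omega", "phi")],
                geometry_flag=g.overall_flag,
            )
        return row


def detect(
    structure: Structure,
    library: TemplateLibrary,
    model: clf.LogisticModel,
    geometry_ref: geo.GeometryReference | None = None,
    search: SearchConfig | None = None,
    sasa_points: int = 500,
    qc_enabled: bool = True,
    evaluation_mode: bool = False,
) -> list[SiteResult]:
    """Programmatic API: all scored candidate sites of one structure."""
    hits = find_matches(structure, library, search or SearchConfig())
    if evaluation_mode:
        hits = exclude_by_identity(hits, structure, library)
    hits = reduce_to_best(hits)
    if not hits:
        return []
    sasa = compute_sasa(structure, n_points=sasa_points)
    results = []
    for hit in hits:
        feats = SiteFeatures(
            rmsd=hit.rmsd,
            r_asa=compute_rasa(structure, hit.site, sasa=sasa),
        )
        pred = clf.predict(
            model, feats,
            site=tuple(r.key for r in hit.site),
            template_id=hit.template_id,
            topology=hit.topology,
        )
        report = None
        if qc_enabled and geometry_ref is not None and pred.is_bond:
            report = geo.assess(hit.site, hit.topology, geometry_ref)
        results.append(
            SiteResult(
                structure_id=structure.id,
                hit=hit,
                features=feats,
                prediction=pred,
                geometry=report,
            )
        )
    return results


def _expand_inputs(paths: list[Path]) -> list[Path]:
    out: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            out.extend(sorted(
                f for f in p.iterdir()
                if f.suffix.lower() in (".pdb", ".cif", ".mmcif", ".ent")
            ))
        else:
            out.append(p)
    return out


def run(config: RunConfig) -> tuple[list[dict], int]:
    """Process every input structure; returns (rows, exit_status).

    Exit status is nonzero only when there are no usable inputs at all.
    """
    inputs = _expand_inputs(config.inputs)
    if not inputs:
        logger.error("no input structures")
        return [], 2

    if config.template_dir is not None:
        library = load_library(config.template_dir)
    else:
        from importlib import resources
        bundled = resources.files("isopeptide_detect.data").joinpath("templates")
        library = load_library(Path(str(bundled)))
    logger.info("template library %s (%d templates)", library.version, len(library))
    model = (
        clf.LogisticModel.load(config.model_path)
        if config.model_path is not None
        else clf.load_default_model()
    )
    if config.threshold is not None:
        model.threshold = config.threshold
    geometry_ref = None
    if config.qc_enabled:
        ref_path = config.geometry_ref_path
        if ref_path is None:
            from importlib import resources
            with resources.as_file(
                resources.files("isopeptide_detect.data").joinpath(
                    "geometry_reference.tsv"
                )
            ) as p:
                geometry_ref = geo.GeometryReference.from_file(p)
        else:
            geometry_ref = geo.GeometryReference.from_file(ref_path)

    rows: list[dict] = []
    n_failed = 0
    for path in inputs:
        t0 = time.perf_counter()
        try:
            structure = read_structure(path)
        except StructureError as exc:
            logger.warning("skipping %s: %s", path, exc)
            n_failed += 1
            continue
        results = detect(
            structure,
            library,
            model,
            geometry_ref=geometry_ref,
            search=config.search,
            sasa_points=config.sasa_points,
            qc_enabled=config.qc_enabled,
            evaluation_mode=config.evaluation_mode,
        )
        rows.extend(r.to_row() for r in results)
        logger.info(
            "%s: %d candidate site(s) in %.2fs",
            structure.id, len(results), time.perf_counter() - t0,
        )
    if n_failed == len(inputs):
        logger.error("all %d input(s) failed to parse", n_failed)
        return rows, 1
    if config.output is not None:
        write_tsv(rows, config.output)
    return rows, 0


def _site_key(row: dict) -> tuple:
    triple = frozenset(
        (str(row["chain"]), int(row[k])) for k in ("r1_bond", "r_cat", "r2_bond")
    )
    return (str(row["structure_id"]), triple)


def _read_table(path: str | Path) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    required = {"structure_id", "chain", "r1_bond", "r_cat", "r2_bond"}
    if not required.issubset(header):
        raise ValueError(f"{path}: missing columns {sorted(required - set(header))}")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:] if line.strip()]


def evaluate(
    prediction_rows: list[dict] | str | Path,
    truth: str | Path | list[dict],
    threshold: float = 0.5,
) -> dict:
    """Site-level precision/recall of predictions against a truth table.

    Sites are matched on (structure id, unordered residue triple).  A
    prediction row counts as positive when its probability strictly exceeds
    ``threshold``.  Precision is None (reported NA) when nothing is
    predicted positive.
    """
    if not isinstance(prediction_rows, list):
        prediction_rows = _read_table(prediction_rows)
    if not isinstance(truth, list):
        truth = _read_table(truth)
    predicted = {
        _site_key(r) for r in prediction_rows
        if r.get("probability") not in (None, "NA")
        and float(r["probability"]) > threshold
    }
    truth_keys = {_site_key(r) for r in truth}
    tp = len(predicted & truth_keys)
    fp = len(predicted - truth_keys)
    fn = len(truth_keys - predicted)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if (tp + fp) > 0 else None,
        "recall": tp / (tp + fn) if (tp + fn) > 0 else None,
    }
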