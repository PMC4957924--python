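"""End-to-end orchestration of the substrate-prediction stages.

``run_predict`` builds the peptide library from a query proteome, trains the
three scoring methods on a training proteome (positives = annotated pY
windows, negatives = background tyrosine windows), scores and ranks every
library peptide and flags the top-fraction consensus.  ``run_filter`` and
``run_pose_eval`` wrap the biological filters and the pose criteria.  Every
run writes a manifest recording parameters, formula identifier, seed and
input checksums, sufficient to reproduce the output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bio_filters import PathwaySets, SubstrateTable, filter_report
from .pose_criteria import (
    ComplexPose,
    PoseParameters,
    ReferenceComplex,
    evaluate_poses,
)
from .seq_scoring import (
    PSSM_FORMULA_ID,
    CandidateRecord,
    build_logo,
    build_pssm,
    classifier_score,
    consensus,
    logo_score,
    pssm_score,
    records_to_frame,
    train_classifier,
)
from .sequence_library import (
    enumerate_background_windows,
    extract_windows,
    read_fasta,
    read_site_annotations,
)

__all__ = ["RunConfig", "PipelineError", "run_predict", "run_filter", "run_pose_eval"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Parameters of a prediction run (paths plus the tunable knobs)."""

    library_fasta: str | Path
    library_sites: str | Path
    train_fasta: str | Path
    train_sites: str | Path
    out_dir: str | Path
    q: float = 0.10
    alpha: float = 0.05
    target_specificity: float = 0.95
    logo_correction: bool = True
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("library_fasta", "library_sites", "train_fasta", "train_sites"):
            path = Path(getattr(self, attr))
            if not path.exists():
                raise PipelineError(f"{attr}: no such file {path}")
        if not 0 < self.q <= 1:
            raise PipelineError("q must be in (0, 1]")
        if self.alpha <= 0:
            raise PipelineError("alpha must be > 0")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, params: dict, inputs: dict) -> Path:
    manifest = {
        "tool": f"ptpscout {__version__}",
        "stage": stage,
        "parameters": params,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()},
    }
    out = out_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def run_predict(config: RunConfig) -> pd.DataFrame:
    """Library extraction, three-method scoring, consensus. Returns the
    candidate table (also written to ``<out_dir>/candidates.tsv``)."""
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    lib_proteins = stage("read library fasta", read_fasta, config.library_fasta)
    lib_sites = stage(
        "read library sites", read_site_annotations, config.library_sites, lib_proteins
    )
    library = stage("extract windows", extract_windows, lib_sites, lib_proteins)

    train_proteins = stage("read training fasta", read_fasta, config.train_fasta)
    train_sites = stage(
        "read training sites", read_site_annotations, config.train_sites, train_proteins
    )
    positives = stage("extract positives", extract_windows, train_sites, train_proteins)
    negatives = stage(
        "enumerate negatives",
        enumerate_background_windows,
        train_proteins,
        train_sites.sites,
    )

    logo = stage("build logo", build_logo, positives, config.logo_correction)
    matrices = stage("build pssm", build_pssm, positives, negatives)
    clf = stage(
        "train classifier",
        train_classifier,
        positives,
        negatives,
        config.target_specificity,
        config.seed,
    )

    records = [
        CandidateRecord(
            window=w,
            score_logo=logo_score(w, logo),
            score_pssm=pssm_score(w, matrices, config.alpha),
            score_clf=classifier_score(w, clf),
        )
        for w in library
    ]
    records = stage("consensus", consensus, records, config.q)
    frame = records_to_frame(records)
    frame.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    _write_manifest(
        out_dir,
        "predict",
        {
            "q": config.q,
            "alpha": config.alpha,
            "pssm_formula": PSSM_FORMULA_ID,
            "target_specificity": config.target_specificity,
            "classifier_threshold": clf.threshold,
            "logo_correction": config.logo_correction,
            "seed": config.seed,
            "n_library": len(library),
            "n_positives": len(positives),
            "n_negatives": len(negatives),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        },
        {
            "library_fasta": config.library_fasta,
            "library_sites": config.library_sites,
            "train_fasta": config.train_fasta,
            "train_sites": config.train_sites,
        },
    )
    return frame


def run_filter(
    candidates: pd.DataFrame,
    substrate_tsv: str | Path,
    gmt_paths: dict[str, str | Path],
    anchor: str,
    anchor_gene: str,
    out_dir: str | Path,
    require_all_collections: bool = False,
) -> pd.DataFrame:
    """Apply the substrate/pathway filters to the genes behind each candidate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = SubstrateTable.from_tsv(substrate_tsv)
    pathways = PathwaySets()
    for name, path in gmt_paths.items():
        pathways.add_gmt(name, path)
    gene_col = "gene" if "gene" in candidates.columns else "genes"
    if gene_col not in candidates.columns:
        raise PipelineError("candidate table has neither a 'gene' nor a 'genes' column")
    genes = sorted(
        {
            g
            for cell in candidates[gene_col].fillna("")
            for g in str(cell).split(",")
            if g
        }
    )
    report = filter_report(
        genes, table, pathways, anchor, anchor_gene, require_all_collections
    )
    report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        "filter",
        {
            "anchor": anchor,
            "anchor_gene": anchor_gene,
            "require_all_collections": require_all_collections,
            "n_genes": len(genes),
        },
        {"substrates": substrate_tsv, **{f"gmt_{k}": v for k, v in gmt_paths.items()}},
    )
    return report


def run_pose_eval(
    pose_paths: list[str | Path],
    reference_pdb: str | Path,
    out_dir: str | Path,
    params: PoseParameters | None = None,
    phosphatase_chain: str = "A",
    peptide_chain: str = "B",
) -> pd.DataFrame:
    """Evaluate each pose PDB against the reference; unreadable poses are
    logged and skipped (error only if none load)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = ReferenceComplex(
        ComplexPose.from_pdb(reference_pdb, phosphatase_chain, peptide_chain)
    )
    poses, failures = [], []
    for path in pose_paths:
        try:
            poses.append(
                (Path(path).name, ComplexPose.from_pdb(path, phosphatase_chain, peptide_chain))
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(f"{path}: {exc}")
    if failures:
        (out / "pose_failures.log").write_text("\n".join(failures) + "\n")
    if not poses:
        raise PipelineError(
            f"no readable poses among {len(pose_paths)} inputs; see pose_failures.log"
        )
    report = evaluate_poses(poses, reference, params)
    report.to_csv(out / "pose_report.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        "pose-eval",
        {**asdict(params or PoseParameters()), "n_poses": len(poses),
         "n_failures": len(failures)},
        {"reference": reference_pdb},
    )
    return report
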