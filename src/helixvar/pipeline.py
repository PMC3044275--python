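"""End-to-end orchestration: generate → invariants → subclass → merge →
propensities → classify.

Stages communicate only through serialized files inside a run directory, so
any stage can be re-run in isolation or fed externally produced inputs
(e.g. invariants computed from real PDB chains instead of the synthetic
corpus).  Every stochastic stage derives its randomness from the single
master seed in the run configuration; rerunning with the same configuration
reproduces all artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, classifier, propensities, subclass_model, synthetic
from .geometry import (
    INVARIANT_NAMES,
    CAlphaTrace,
    compute_invariants,
    extract_octapeptides,
)

__all__ = ["RunConfig", "run", "STAGES"]

log = logging.getLogger("helixvar")

STAGES = ("generate", "invariants", "subclass", "merge", "propensity", "classify")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "helixvar_run"
    seed: int = 0
    n_helices: int = 2000
    k: int = 5
    variance_threshold: float = 0.80
    max_training_length: int = 15
    folds: int = 10
    C: float = 1.0
    write_pdb: bool = False
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_helices < 10:
            raise ValueError("n_helices must be >= 10")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Stage implementations


def stage_generate(cfg: RunConfig) -> None:
    """Generate the labeled synthetic corpus and serialize it."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = synthetic.generate_dataset(
        synthetic.DatasetConfig(n_helices=cfg.n_helices), seed=cfg.seed,
        out_dir=out / "corpus" if cfg.write_pdb else None)
    rows = []
    coord_arrays = {}
    for i, (trace, seg, label, chain) in enumerate(zip(
            dataset.traces, dataset.segments, dataset.labels,
            dataset.chain_sequences)):
        hid = f"helix{i:05d}"
        rows.append({
            "helix_id": hid, "subclass": label, "length": seg.length,
            "sequence": seg.sequence, "flank_before": seg.flank_before,
            "flank_after": seg.flank_after, "chain_sequence": chain,
        })
        coord_arrays[hid] = trace.coords
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    np.savez_compressed(out / "coords.npz", **coord_arrays)
    with open(out / "sequences.fasta", "w") as fh:
        for r in rows:
            fh.write(f">{r['helix_id']} subclass={r['subclass']} "
                     f"flank_before={r['flank_before']} "
                     f"flank_after={r['flank_after']}\n{r['sequence']}\n")
    log.info("generate: %d helices (%s)", len(manifest),
             dict(manifest["subclass"].value_counts()))


def _load_traces(out: Path) -> dict[str, CAlphaTrace]:
    import warnings

    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    traces = {}
    with np.load(out / "coords.npz") as npz:
        for _, row in manifest.iterrows():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # noisy traces are expected
                traces[row["helix_id"]] = CAlphaTrace(
                    coords=npz[row["helix_id"]], sequence=row["sequence"],
                    source_id=row["helix_id"])
    return traces


def stage_invariants(cfg: RunConfig) -> None:
    """Slide octapeptide windows over every trace and tabulate invariants."""
    out = Path(cfg.out_dir)
    traces = _load_traces(out)
    rows = []
    for hid, trace in traces.items():
        for w in extract_octapeptides(trace):
            rec = {"helix_id": hid, "start": w.start}
            rec.update(compute_invariants(w).to_dict())
            rows.append(rec)
    pd.DataFrame(rows).to_csv(out / "invariants.tsv", sep="\t", index=False)
    log.info("invariants: %d windows x %d invariants", len(rows),
             len(INVARIANT_NAMES))


def stage_subclass(cfg: RunConfig) -> None:
    """Standardize, project, fit the k-Gaussian mixture and assign windows."""
    out = Path(cfg.out_dir)
    inv = pd.read_csv(out / "invariants.tsv", sep="\t")
    X = inv[list(INVARIANT_NAMES)].to_numpy()
    std = subclass_model.fit_standardizer(X)
    Z = std.transform(X)
    pca = subclass_model.fit_pca(Z, cfg.variance_threshold)
    Y = pca.project(Z)
    gmm = subclass_model.fit_gmm(Y, cfg.k, seed=cfg.seed)
    subclass_model.save_model(out / "model.npz", std, pca, gmm)
    post = gmm.predict_proba(Y)
    comp = post.argmax(axis=1)
    assign_df = inv[["helix_id", "start"]].copy()
    assign_df["component"] = comp
    assign_df["max_posterior"] = post.max(axis=1)
    assign_df.to_csv(out / "assignments.tsv", sep="\t", index=False)

    # map components to generator subclass names by majority vote (synthetic
    # corpora only; on real data components keep numeric ids)
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    truth = assign_df.merge(manifest[["helix_id", "subclass"]], on="helix_id")
    mapping = {int(c): str(g["subclass"].mode()[0])
               for c, g in truth.groupby("component")}
    table1 = []
    for c in range(cfg.k):
        sel = inv[comp == c]
        table1.append({
            "component": c, "mapped_subclass": mapping.get(c, str(c)),
            "n_windows": len(sel),
            "d18_mean": sel["d_1_8"].mean(), "d18_sd": sel["d_1_8"].std(ddof=0),
            "A158_mean": sel["A_1_5_8"].mean(),
            "A158_sd": sel["A_1_5_8"].std(ddof=0),
        })
    pd.DataFrame(table1).to_csv(out / "gross_invariants_by_subclass.tsv",
                                sep="\t", index=False)
    summary = {
        "k": cfg.k,
        "n_retained_pcs": pca.s,
        "explained_variance": float(
            pca.explained_variance_fraction[: pca.s].sum()),
        "mixing_weights": gmm.weights.tolist(),
        "component_mapping": mapping,
        "log_likelihood": float(gmm.log_likelihood_trace[-1]),
        "em_iterations": len(gmm.log_likelihood_trace),
    }
    with open(out / "subclass_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("subclass: k=%d, s=%d PCs, weights=%s", cfg.k, pca.s,
             np.round(gmm.weights, 3).tolist())


def _merged_segments(cfg: RunConfig, mode: str) -> list[assembly.HelixSegment]:
    out = Path(cfg.out_dir)
    assign_df = pd.read_csv(out / "assignments.tsv", sep="\t")
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t").set_index("helix_id")
    with open(out / "subclass_summary.json") as fh:
        mapping = {int(k): v for k, v in
                   json.load(fh)["component_mapping"].items()}
    traces = _load_traces(out)
    segments = []
    for hid, grp in assign_df.groupby("helix_id", sort=True):
        grp = grp.sort_values("start")
        windows = extract_octapeptides(traces[hid])
        labels = [mapping.get(int(c), str(c)) for c in grp["component"]]
        chain = manifest.loc[hid, "chain_sequence"]
        for seg in assembly.merge_windows(windows, labels, mode=mode):
            shifted = assembly.HelixSegment(
                source_id=hid,
                start=seg.start + assembly.FLANK_WIDTH,
                end=seg.end + assembly.FLANK_WIDTH,
                sequence=seg.sequence,
                subclass_labels=seg.subclass_labels,
            )
            segments.append(assembly.attach_flanks(shifted, chain))
    return segments


def _segments_to_frame(segments) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "source_id": s.source_id, "start": s.start, "end": s.end,
            "length": s.length, "purity_label": s.purity_label,
            "window_labels": ",".join(map(str, s.subclass_labels)),
            "sequence": s.sequence, "flank_before": s.flank_before,
            "flank_after": s.flank_after,
        }
        for s in segments
    ])


def stage_merge(cfg: RunConfig) -> None:
    """Merge assigned windows into helices (both modes) with flanks."""
    out = Path(cfg.out_dir)
    for mode in ("within", "across"):
        segs = _merged_segments(cfg, mode)
        _segments_to_frame(segs).to_csv(out / f"segments_{mode}.tsv",
                                        sep="\t", index=False)
        log.info("merge[%s]: %d segments", mode, len(segs))


def stage_propensity(cfg: RunConfig) -> None:
    """Propensity tables and length distribution from within-merged helices."""
    out = Path(cfg.out_dir)
    segs = pd.read_csv(out / "segments_within.tsv", sep="\t")
    groups = {s: g["sequence"].tolist()
              for s, g in segs.groupby("purity_label") if s != assembly.MIXED}
    overall = propensities.overall_propensity(groups)
    positional = propensities.positional_propensity(groups)
    overall.values.to_csv(out / "overall_propensity.tsv", sep="\t")
    positional.values.to_csv(out / "positional_propensity.tsv", sep="\t")
    propensities.length_distribution(
        {s: g["length"].tolist() for s, g in segs.groupby("purity_label")}
    ).to_csv(out / "length_distribution.tsv", sep="\t")
    preferred = []
    for s in groups:
        for pos in (propensities.N_POSITIONS + propensities.C_POSITIONS
                    + propensities.M_POSITIONS):
            ranked = propensities.rank_preferred(positional, s, pos)
            preferred.append({"subclass": s, "position": pos,
                              "preferred": "/".join(ranked[:5])})
    pd.DataFrame(preferred).to_csv(out / "preferred_amino_acids.tsv",
                                   sep="\t", index=False)
    log.info("propensity: %d subclasses", len(groups))


def stage_classify(cfg: RunConfig) -> None:
    """Encode generator-labeled helices, train the linear SVM, evaluate."""
    out = Path(cfg.out_dir)
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    positives, negatives = [], []
    for _, row in manifest.iterrows():
        if row["length"] > cfg.max_training_length:
            continue
        nwin = row["length"] - 7
        seg = assembly.HelixSegment(
            source_id=row["helix_id"], start=assembly.FLANK_WIDTH + 1,
            end=assembly.FLANK_WIDTH + row["length"],
            sequence=row["sequence"],
            subclass_labels=(row["subclass"],) * nwin)
        seg = assembly.attach_flanks(seg, row["chain_sequence"])
        (positives if row["subclass"] == "regular" else negatives).append(seg)
    D = classifier.build_training_set(positives, negatives,
                                      max_length=cfg.max_training_length)
    cv = classifier.evaluate(D, folds=cfg.folds, seed=cfg.seed, C=cfg.C)
    holdout = classifier.holdout_evaluate(D, seed=cfg.seed, C=cfg.C)
    model = classifier.train(D, C=cfg.C, seed=cfg.seed)
    weights = classifier.feature_weights(model).sort_values()
    weights.to_csv(out / "feature_weights.tsv", sep="\t")
    metrics = {
        "n_examples": len(D),
        "n_positive": int((D.y == 1).sum()),
        "n_negative": int((D.y == -1).sum()),
        "cv": {"folds": cfg.folds, "precision": cv.precision,
               "recall": cv.recall, "f1": cv.f1,
               "confusion": cv.confusion,
               "per_fold_f1": [m.f1 for m in cv.per_fold]},
        "holdout_70_30": {"precision": holdout.precision,
                          "recall": holdout.recall, "f1": holdout.f1},
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    log.info("classify: n=%d (+%d/-%d) CV P=%.3f R=%.3f F1=%.3f",
             len(D), metrics["n_positive"], metrics["n_negative"],
             cv.precision, cv.recall, cv.f1)


_STAGE_FUNCS = {
    "generate": stage_generate,
    "invariants": stage_invariants,
    "subclass": stage_subclass,
    "merge": stage_merge,
    "propensity": stage_propensity,
    "classify": stage_classify,
}


def run(config: RunConfig) -> Path:
    """Execute the configured stages in order; abort naming the failed stage.

    Returns the run directory.  Partial artifacts of a failed run are left
    in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO,
                            format="%(asctime)s %(name)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        config.to_yaml(out / "config.yaml")
        log.info("run: seed=%d stages=%s", config.seed, list(config.stages))
        for stage in STAGES:
            if stage not in config.stages:
                continue
            try:
                _STAGE_FUNCS[stage](config)
            except Exception as exc:
                log.error("stage %r failed: %s", stage, exc)
                raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
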