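"""End-to-end orchestration: split → featurize/process → train → calibrate
→ evaluate → applicability domain → interpretability.

The splitter produces disjoint, exhaustive train/validation/test index
sets of exact target sizes (largest-remainder rounding of the requested
fractions).  Stratified mode uses iterative stratification: labels are
processed rarest-first and each positive sample goes to the split whose
desired count for that label is furthest from satisfied, subject to
overall capacity — keeping every label's positive rate in every split
close to its global rate.  Calibration sees validation rows only; test
rows are scored exactly once, after thresholds are frozen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ad import assess_ad
from .baselines import BaselineSpec, BinaryRelevanceClassifier
from .calibration import ThresholdCalibrator, gain_report
from .containers import LabelMatrix, as_label_array
from .descriptors import StrategyAPreprocessor, StrategyBSelector, StrategyCReducer
from .evaluation import compute_metrics, macro_f1_score
from .featurization import smiles_list_to_graphs
from .gnn import GNNConfig, GNNClassifier
from .interpret import fragment_report
from .synthetic import DescriptorNoiseSpec, GenerationConfig, make_dataset

log = logging.getLogger("odorpred")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _target_sizes(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n rows into len(fractions) splits."""
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    for _ in range(n - sum(sizes)):
        rem = [r - s for r, s in zip(raw, sizes)]
        sizes[int(np.argmax(rem))] += 1
    return sizes


def make_split(labels, fractions=(0.64, 0.16, 0.20), mode="per_label_stratified", seed=0):
    """Split row indices into (train, validation, test).

    ``per_label_stratified`` uses iterative stratification; a label with
    fewer than 3 positives makes stratification infeasible and triggers a
    random fallback with a warning.  Deterministic given the seed."""
    Y = as_label_array(labels)
    n = Y.shape[0]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    sizes = _target_sizes(n, fractions)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    if mode == "per_label_stratified" and (Y.sum(axis=0) < 3).any():
        warnings.warn("a label has fewer than 3 positives; falling back to a random split")
        mode = "random"
    if mode == "random":
        order = rng.permutation(n)
        out = []
        start = 0
        for s in sizes:
            out.append(np.sort(order[start : start + s]))
            start += s
        return tuple(out)
    if mode != "per_label_stratified":
        raise ValueError(f"unknown split mode {mode!r}")

    capacity = np.array(sizes, dtype=float)
    desired = np.outer(Y.sum(axis=0), fractions).T  # (3, K) desired positives
    assignment = np.full(n, -1, dtype=int)
    remaining = set(range(n))
    # labels rarest-first; within a label, samples in random order
    while True:
        counts = [
            (Y[list(remaining), k].sum(), k) for k in range(Y.shape[1])
        ] if remaining else []
        counts = [(c, k) for c, k in counts if c > 0]
        if not counts:
            break
        _, k = min(counts)
        rows = [i for i in remaining if Y[i, k] == 1]
        for i in rng.permutation(rows):
            open_splits = np.flatnonzero(capacity > 0)
            j = open_splits[np.argmax(desired[open_splits, k])]
            assignment[i] = j
            capacity[j] -= 1
            desired[j] -= Y[i]
            remaining.discard(int(i))
    for i in rng.permutation(sorted(remaining)):  # all-negative rows: fill capacity
        j = int(np.argmax(capacity))
        assignment[i] = j
        capacity[j] -= 1
    splits = tuple(np.flatnonzero(assignment == j) for j in range(len(fractions)))
    _check_stratification(Y, splits)
    return splits


def _check_stratification(Y, splits, tol=0.05):
    global_rate = Y.mean(axis=0)
    for j, idx in enumerate(splits):
        if idx.size == 0:
            continue
        dev = np.abs(Y[idx].mean(axis=0) - global_rate)
        if (dev > tol).any():
            warnings.warn(
                f"split {j}: per-label positive rate deviates by up to "
                f"{dev.max():.3f} from the global rate"
            )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One end-to-end run: data source, split, model, toggles, seed, outputs."""

    molecules_csv: str | None = None
    descriptors_csv: str | None = None
    synthetic: GenerationConfig | None = None
    descriptor_spec: DescriptorNoiseSpec | None = None
    split_fractions: tuple = (0.64, 0.16, 0.20)
    split_mode: str = "per_label_stratified"
    gnn: GNNConfig | None = None
    baseline: BaselineSpec | None = None
    strategy: str = "a"  # descriptor strategy for the baseline branch: a | b | c_pca | c_kpca
    calibration_grid: list | None = None
    run_ad: bool = True
    run_interpret: bool = True
    interpret_samples: int = 30
    seed: int = 0
    outdir: str = "runs/run"

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.gnn is None and self.baseline is None:
            raise ValueError("at least one model block (gnn or baseline) is required")
        if self.molecules_csv is None and self.synthetic is None:
            raise ValueError("either molecules_csv or a synthetic block is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if isinstance(kw.get("synthetic"), dict):
            kw["synthetic"] = GenerationConfig(**kw["synthetic"])
        if isinstance(kw.get("descriptor_spec"), dict):
            kw["descriptor_spec"] = DescriptorNoiseSpec(**kw["descriptor_spec"])
        if isinstance(kw.get("gnn"), dict):
            kw["gnn"] = GNNConfig(**kw["gnn"])
        if isinstance(kw.get("baseline"), dict):
            kw["baseline"] = BaselineSpec(**kw["baseline"])
        if "split_fractions" in kw:
            kw["split_fractions"] = tuple(kw["split_fractions"])
        return cls(**kw)

    def resolved(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            d[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return d


def quick_profile(seed: int = 0, outdir: str = "runs/quick") -> RunConfig:
    """A reduced synthetic profile: 300 molecules, one small GCN."""
    return RunConfig(
        synthetic=GenerationConfig(n_molecules=300, seed=seed),
        gnn=GNNConfig(hidden_dim=32, n_layers=2, max_epochs=30, patience=10, seed=seed),
        interpret_samples=20,
        seed=seed,
        outdir=outdir,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _load_data(config: RunConfig):
    if config.molecules_csv is not None:
        mols = pd.read_csv(config.molecules_csv)
        smiles = mols["smiles"].tolist()
        label_names = [c for c in mols.columns if c != "smiles"]
        labels = LabelMatrix(mols[label_names].to_numpy(), label_names)
        table = pd.read_csv(config.descriptors_csv) if config.descriptors_csv else None
    else:
        spec = config.descriptor_spec
        if spec is None and config.baseline is not None:
            spec = DescriptorNoiseSpec()
        smiles, labels, table = make_dataset(config.synthetic, spec)
    return smiles, labels, table


def _baseline_branch(config, table, labels, tr, va, te, outdir):
    """Process descriptors per the chosen strategy and train the baseline."""
    pre = StrategyAPreprocessor().fit(table.iloc[tr])
    X = pre.transform(table)
    (outdir / "preprocess_report.json").write_text(
        json.dumps(pre.report_.to_dict(), indent=2, default=float)
    )
    Y = labels.values
    spec = config.baseline
    strategy = config.strategy
    if strategy == "a":
        Xs = {name: X for name in labels.label_names}
    elif strategy == "b":
        sel = StrategyBSelector(random_state=spec.seed).fit(
            X.iloc[tr], Y[tr], label_names=labels.label_names
        )
        (outdir / "selection_trace.json").write_text(
            json.dumps({k: v for k, v in sel.trace_.items() if isinstance(v, list)}, indent=2)
        )
        Xs = {
            name: X[sel.support_[name]] if sel.support_[name] else X
            for name in labels.label_names
        }
    elif strategy in ("c_pca", "c_kpca"):
        red = StrategyCReducer(method=strategy.split("_")[1], random_state=spec.seed).fit(X.iloc[tr])
        Xr = pd.DataFrame(red.transform(X), index=X.index)
        Xs = {name: Xr for name in labels.label_names}
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    val_scores = np.zeros((len(va), len(labels.label_names)))
    test_scores = np.zeros((len(te), len(labels.label_names)))
    train_vectors, test_vectors = X.iloc[tr].to_numpy(), X.iloc[te].to_numpy()
    for k, name in enumerate(labels.label_names):
        Xk = Xs[name].to_numpy(dtype=float)
        clf = BinaryRelevanceClassifier(
            model_kind=spec.model_kind, grid=spec.grid, cv_folds=spec.cv_folds, seed=spec.seed
        ).fit(Xk[tr], Y[tr][:, [k]], label_names=[name])
        val_scores[:, k] = clf.predict_proba(Xk[va])[:, 0]
        test_scores[:, k] = clf.predict_proba(Xk[te])[:, 0]
    return val_scores, test_scores, train_vectors, test_vectors, None


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the output directory.

    Emits metrics (JSON + CSV), calibrated thresholds, the before/after
    gain report, the AD report, per-label fragment tables, the training
    history and the resolved configuration.  Reruns with an identical
    configuration reproduce the metrics bit for bit."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> Path:
    import odorpred

    log.info("seed=%d version=%s", config.seed, getattr(odorpred, "__version__", "dev"))
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.resolved(), sort_keys=False))

    smiles, labels, table = _load_data(config)
    Y = labels.values
    tr, va, te = make_split(labels, config.split_fractions, config.split_mode, config.seed)
    np.savetxt(outdir / "split_train.txt", tr, fmt="%d")
    np.savetxt(outdir / "split_val.txt", va, fmt="%d")
    np.savetxt(outdir / "split_test.txt", te, fmt="%d")
    log.info("split sizes: %d/%d/%d", len(tr), len(va), len(te))

    model = None
    graphs = None
    if config.gnn is not None:
        graphs = smiles_list_to_graphs(smiles)
        model = GNNClassifier(**config.gnn.to_dict())
        model.fit(
            [graphs[i] for i in tr], Y[tr],
            validation_data=([graphs[i] for i in va], Y[va]),
            label_names=labels.label_names,
        )
        pd.DataFrame(model.history_).to_json(outdir / "history.jsonl", orient="records", lines=True)
        val_scores = model.predict_proba([graphs[i] for i in va])
        test_scores = model.predict_proba([graphs[i] for i in te])
        train_vectors = model.embed([graphs[i] for i in tr])
        test_vectors = model.embed([graphs[i] for i in te])
    else:
        if table is None:
            raise ValueError("a baseline model needs a descriptor table")
        val_scores, test_scores, train_vectors, test_vectors, _ = _baseline_branch(
            config, table, labels, tr, va, te, outdir
        )

    # calibration on validation rows only
    cal = ThresholdCalibrator(grid=config.calibration_grid).fit(
        val_scores, Y[va], label_names=labels.label_names
    )
    (outdir / "thresholds.json").write_text(json.dumps(cal.threshold_vector().to_dict(), indent=2))

    pred_before = (test_scores >= 0.5).astype(int)
    pred_after = cal.transform(test_scores)
    before = compute_metrics(pred_before, Y[te], scores=test_scores, label_names=labels.label_names)
    after = compute_metrics(pred_after, Y[te], scores=test_scores, label_names=labels.label_names)
    after.per_label.to_csv(outdir / "metrics_per_label.csv")
    (outdir / "metrics.json").write_text(
        json.dumps({"before_calibration": before.to_dict(), "after_calibration": after.to_dict()},
                   indent=2, default=float)
    )
    gains = gain_report(
        before.per_label["f1"].tolist() + [before.macro_f1],
        after.per_label["f1"].tolist() + [after.macro_f1],
        names=labels.label_names + ["macro"],
    )
    gains.to_csv(outdir / "gain_report.csv")
    log.info("test macro F1: before=%.4f after=%.4f", before.macro_f1, after.macro_f1)

    if config.run_ad:
        report = assess_ad(
            [smiles[i] for i in tr], [smiles[i] for i in te], train_vectors, test_vectors
        )
        report.per_sample.to_csv(outdir / "ad_per_sample.csv", index=False)
        (outdir / "ad_summary.json").write_text(json.dumps(report.summary, indent=2, default=float))

    if config.run_interpret and model is not None:
        tables = fragment_report(
            model, [graphs[i] for i in te], Y[te], pred_after,
            label_names=labels.label_names, n_samples=config.interpret_samples,
        )
        for name, t in tables.items():
            t.to_csv(outdir / f"fragments_{name}.csv")
    return outdir
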