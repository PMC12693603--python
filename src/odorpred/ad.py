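"""Applicability-domain (AD) assessment.

Two complementary views of whether a test molecule lies inside the
chemical space a model was trained on:

* **Tanimoto similarity** on 2048-bit radius-2 circular (Morgan/ECFP4)
  fingerprints: a test molecule is in-domain when its maximum Tanimoto
  similarity to any training molecule reaches 0.5.
* **Feature-space distance**: minimum Euclidean distance from the test
  vector (processed descriptors for tabular models, pooled graph
  embeddings for GNNs) to the training set, compared against the 95th
  percentile of the training set's leave-one-out nearest-neighbour
  distances.  The LOO-NN reading is the only self-consistent way to turn
  "training set distances" into a min-distance threshold; percentiles use
  linear interpolation.

The combined judgment is the conservative AND of the two flags; the
agreement rate is the fraction of samples where the two methods concur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.spatial.distance import cdist

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


@dataclass
class ADReport:
    """Per-sample AD flags plus the summary statistics of both methods."""

    per_sample: pd.DataFrame  # max_tanimoto, tanimoto_in, min_distance, distance_in, combined_in
    distance_threshold: float
    tanimoto_threshold: float

    @property
    def summary(self) -> dict:
        df = self.per_sample
        return {
            "tanimoto_in_domain_pct": 100.0 * df["tanimoto_in"].mean(),
            "distance_in_domain_pct": 100.0 * df["distance_in"].mean(),
            "combined_in_domain_pct": 100.0 * df["combined_in"].mean(),
            "agreement_pct": 100.0 * (df["tanimoto_in"] == df["distance_in"]).mean(),
            "mean_max_similarity": float(df["max_tanimoto"].mean()),
            "min_max_similarity": float(df["max_tanimoto"].min()),
            "mean_min_distance": float(df["min_distance"].mean()),
            "distance_threshold": self.distance_threshold,
        }


def _fingerprints(smiles_list):
    fps = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES at row {i}: {smi!r}")
        fps.append(_MORGAN.GetFingerprint(mol))
    return fps


def tanimoto_similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto similarity of two molecules' ECFP4 fingerprints."""
    fa, fb = _fingerprints([smiles_a, smiles_b])
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def tanimoto_ad(train_smiles, test_smiles, threshold: float = 0.5):
    """Max-similarity AD: per test molecule, (max Tanimoto to train, flag)."""
    if len(train_smiles) == 0:
        raise ValueError("empty training set")
    train_fps = _fingerprints(train_smiles)
    test_fps = _fingerprints(test_smiles)
    max_sim = np.array(
        [max(DataStructs.BulkTanimotoSimilarity(fp, train_fps)) for fp in test_fps]
    )
    return max_sim, max_sim >= threshold


def distance_ad(train_vectors, test_vectors, percentile: float = 95.0):
    """Min-distance AD in a feature or embedding space.

    The threshold is the given percentile of the training set's
    leave-one-out nearest-neighbour distances; a test sample is in-domain
    when its minimum distance to the training set does not exceed it.
    Returns (min_dist, threshold, flags)."""
    X = np.asarray(train_vectors, dtype=float)
    T = np.asarray(test_vectors, dtype=float)
    if X.ndim != 2 or T.ndim != 2 or X.shape[1] != T.shape[1]:
        raise ValueError("train/test vectors must be 2-D with equal width")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors for LOO distances")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    loo_nn = D.min(axis=1)
    threshold = float(np.percentile(loo_nn, percentile))
    min_dist = cdist(T, X).min(axis=1)
    return min_dist, threshold, min_dist <= threshold


def combine_ad(tanimoto_flags, distance_flags):
    """Conservative AND of the two per-sample flags, plus their agreement."""
    a = np.asarray(tanimoto_flags, dtype=bool)
    b = np.asarray(distance_flags, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must be aligned")
    return a & b, float((a == b).mean())


def assess_ad(
    train_smiles, test_smiles, train_vectors, test_vectors,
    tanimoto_threshold: float = 0.5, distance_percentile: float = 95.0,
) -> ADReport:
    """Run both AD methods and the combined judgment."""
    max_sim, tflags = tanimoto_ad(train_smiles, test_smiles, tanimoto_threshold)
    min_dist, dthresh, dflags = distance_ad(train_vectors, test_vectors, distance_percentile)
    combined, _ = combine_ad(tflags, dflags)
    per_sample = pd.DataFrame(
        {
            "max_tanimoto": max_sim,
            "tanimoto_in": tflags,
            "min_distance": min_dist,
            "distance_in": dflags,
            "combined_in": combined,
        }
    )
    return ADReport(per_sample=per_sample, distance_threshold=dthresh,
                    tanimoto_threshold=tanimoto_threshold)
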