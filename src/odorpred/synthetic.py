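"""Synthetic odor datasets with planted structure–odor rules.

Molecules are assembled by a fragment grammar — a scaffold (linear carbon
chain, benzene, cyclopentane or cyclohexane) decorated with functional
groups (ester, aldehyde, ketone, alcohol, thiol, amine, methyl, halogens,
phosphine, sodium alkoxide) — so every output is a valid molecule over the
9-element vocabulary {C, N, O, S, F, Cl, Br, P, Na} without rejection
sampling.  Binary odor labels are planted from SMARTS rules: a label fires
with the rule's activation probability when the pattern matches and with a
small background probability otherwise, yielding the imbalanced label
frequencies (~13–31% positives) typical of curated odor data.  A
descriptor table mimics a commercial descriptor panel at reduced width:
a few columns are exact functions of structure (so selection methods have
true signal to find), the rest are scaled noise with tiered missingness
and injected outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .containers import LabelMatrix

DEFAULT_LABELS = ["fruity", "green", "sweet", "floral", "woody", "herbal"]

#: label → (SMARTS pattern, activation probability, background probability).
#: The chemistry mirrors classic structure–odor associations: esters are
#: fruity, aldehydes green, hydroxyls sweet, ketones floral, thiols woody/
#: smoky, aromatic rings herbal.
DEFAULT_RULE_TABLE = {
    "fruity": ("[CX3](=[OX1])[OX2H0][#6]", 0.90, 0.03),
    "green": ("[CX3H1]=[OX1]", 0.90, 0.03),
    "sweet": ("[OX2H]", 0.90, 0.03),
    "floral": ("[#6][CX3](=[OX1])[#6]", 0.90, 0.03),
    "woody": ("[SX2H]", 0.90, 0.03),
    "herbal": ("c1ccccc1", 0.90, 0.03),
}

_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE}

#: decoration → (atom symbols, bonds as (i, j, order), attachment atom index)
DECORATIONS = {
    "methyl": (["C"], [], 0),
    "ester": (["C", "O", "O", "C"], [(0, 1, 2), (0, 2, 1), (2, 3, 1)], 0),
    "aldehyde": (["C", "O"], [(0, 1, 2)], 0),
    "ketone": (["C", "O", "C"], [(0, 1, 2), (0, 2, 1)], 0),
    "alcohol": (["O"], [], 0),
    "thiol": (["S"], [], 0),
    "amine": (["N"], [], 0),
    "fluoro": (["F"], [], 0),
    "chloro": (["Cl"], [], 0),
    "bromo": (["Br"], [], 0),
    "phosphino": (["P"], [], 0),
    "sodium_oxy": (["O", "Na"], [(0, 1, 1)], 0),
}

#: scaffold SMILES and sampling weights; chains dominate, aromatics are the
#: minority so the aromatic-ring label stays the rarest.
SCAFFOLDS = ["CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "c1ccccc1", "C1CCCCC1", "C1CCCC1"]
SCAFFOLD_WEIGHTS = [0.08, 0.10, 0.12, 0.12, 0.10, 0.06, 0.12, 0.16, 0.14]

#: decoration sampling weights, tuned once so the planted rules fire at
#: frequencies spanning the ~13–31% band of the six default labels.
DECORATION_WEIGHTS = {
    "methyl": 0.145,
    "ester": 0.185,
    "aldehyde": 0.160,
    "alcohol": 0.145,
    "ketone": 0.105,
    "thiol": 0.080,
    "amine": 0.060,
    "fluoro": 0.030,
    "chloro": 0.030,
    "bromo": 0.020,
    "phosphino": 0.020,
    "sodium_oxy": 0.020,
}


@dataclass
class GenerationConfig:
    """Configuration of the molecule/label generator."""

    n_molecules: int = 100
    seed: int = 0
    label_names: list = field(default_factory=lambda: list(DEFAULT_LABELS))
    rule_table: dict = field(default_factory=lambda: dict(DEFAULT_RULE_TABLE))
    target_frequency_range: tuple = (0.129, 0.309)
    scaffolds: list | None = None        # restrict the grammar (None = full)
    decorations: list | None = None
    n_decorations_range: tuple = (1, 3)

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be positive")
        if len(self.label_names) < 2:
            raise ValueError("need at least two labels")
        for name in self.label_names:
            if name not in self.rule_table:
                raise ValueError(f"no rule for label {name!r}")
            _, act, bg = self.rule_table[name]
            if not act > bg:
                raise ValueError(f"rule {name!r}: activation prob must exceed background prob")


@dataclass
class DescriptorNoiseSpec:
    """Noise model of the synthetic descriptor table."""

    n_descriptors: int = 100
    missing_tier_fractions: tuple = (0.4, 0.2, 0.1)  # cols with <5%, 5–30%, >30% missing
    outlier_rate: float = 0.01
    scale_range: tuple = (1e-2, 1e6)

    def __post_init__(self):
        if self.n_descriptors < 10:
            raise ValueError("need at least 10 descriptors")
        if sum(self.missing_tier_fractions) > 1 + 1e-12:
            raise ValueError("missing tier fractions must sum to at most 1")


def _build_molecule(rng: np.random.Generator, config: GenerationConfig) -> str:
    scaffolds = config.scaffolds if config.scaffolds is not None else SCAFFOLDS
    if config.scaffolds is None:
        w = np.array(SCAFFOLD_WEIGHTS)
        scaffold = scaffolds[rng.choice(len(scaffolds), p=w / w.sum())]
    else:
        scaffold = scaffolds[rng.integers(len(scaffolds))]
    mol = Chem.RWMol(Chem.MolFromSmiles(scaffold))

    deco_names = list(config.decorations) if config.decorations is not None else list(DECORATION_WEIGHTS)
    if config.decorations is None:
        weights = np.array([DECORATION_WEIGHTS[d] for d in deco_names])
    else:
        weights = np.ones(len(deco_names))
    weights = weights / weights.sum()

    lo, hi = config.n_decorations_range
    n_dec = int(rng.integers(lo, hi + 1))
    for _ in range(n_dec):
        name = deco_names[rng.choice(len(deco_names), p=weights)]
        atoms, bonds, attach = DECORATIONS[name]
        # eligible attachment sites: carbons with spare valence
        # (aromatic carbon: two ring bonds + at most one substituent;
        # aliphatic carbon: bond-order sum below 4)
        sites = []
        for a in mol.GetAtoms():
            if a.GetSymbol() != "C":
                continue
            if a.GetIsAromatic():
                if a.GetDegree() < 3:
                    sites.append(a.GetIdx())
            elif sum(int(b.GetBondTypeAsDouble()) for b in a.GetBonds()) < 4:
                sites.append(a.GetIdx())
        if not sites:
            break
        site = int(sites[rng.integers(len(sites))])
        new_idx = [mol.AddAtom(Chem.Atom(sym)) for sym in atoms]
        for i, j, order in bonds:
            mol.AddBond(new_idx[i], new_idx[j], _BOND[order])
        mol.AddBond(site, new_idx[attach], Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_molecules(config: GenerationConfig) -> list[str]:
    """Generate ``config.n_molecules`` valid SMILES strings, deterministically."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    out = []
    for _ in range(config.n_molecules):
        for _attempt in range(5):  # grammar output is valid by construction;
            try:                   # the retry guards exotic user grammars
                out.append(_build_molecule(rng, config))
                break
            except Exception:
                continue
        else:
            raise RuntimeError("fragment grammar failed to produce a valid molecule")
    return out


def plant_labels(smiles: list[str], config: GenerationConfig) -> LabelMatrix:
    """Plant binary labels from the SMARTS rule table.

    Label k fires with the rule's activation probability when the molecule
    matches its SMARTS, else with the background probability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    patterns = {}
    for name in config.label_names:
        smarts, _, _ = config.rule_table[name]
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for label {name!r}: {smarts!r}")
        patterns[name] = patt
    n, k = len(smiles), len(config.label_names)
    Y = np.zeros((n, k), dtype=np.int64)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES at row {i}: {smi!r}")
        for j, name in enumerate(config.label_names):
            _, act, bg = config.rule_table[name]
            p = act if mol.HasSubstructMatch(patterns[name]) else bg
            Y[i, j] = int(rng.random() < p)
    return LabelMatrix(Y, list(config.label_names))


def rule_match_matrix(smiles: list[str], rule_table: dict, label_names: list[str]) -> np.ndarray:
    """(n, K) binary matrix: does molecule i match rule k's SMARTS."""
    patterns = [Chem.MolFromSmarts(rule_table[name][0]) for name in label_names]
    M = np.zeros((len(smiles), len(label_names)), dtype=np.int64)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES at row {i}: {smi!r}")
        for j, patt in enumerate(patterns):
            M[i, j] = int(mol.HasSubstructMatch(patt))
    return M


def synth_descriptor_table(
    smiles: list[str],
    spec: DescriptorNoiseSpec,
    seed: int,
    rule_table: dict | None = None,
    label_names: list[str] | None = None,
) -> pd.DataFrame:
    """Build a descriptor table: structure-derived columns plus scaled noise.

    Structure-derived columns (heavy-atom count, ring count, heteroatom and
    aromatic-atom counts, and one rule-match indicator per label) are exact,
    so feature selection has a planted signal to recover.  Noise columns get
    heterogeneous scales, tiered missingness (only noise columns may fall in
    the >30%-missing tier) and injected outliers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    rule_table = rule_table if rule_table is not None else dict(DEFAULT_RULE_TABLE)
    label_names = label_names if label_names is not None else [n for n in DEFAULT_LABELS if n in rule_table]

    n = len(smiles)
    cols: dict[str, np.ndarray] = {}
    heavy, rings, hetero, aromatic = [], [], [], []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"invalid SMILES at row {i}: {smi!r}")
        heavy.append(mol.GetNumHeavyAtoms())
        rings.append(mol.GetRingInfo().NumRings())
        hetero.append(sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H")))
        aromatic.append(sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()))
    cols["heavy_atom_count"] = np.array(heavy, dtype=float)
    cols["ring_count"] = np.array([int(r) for r in rings], dtype=float)
    cols["heteroatom_count"] = np.array(hetero, dtype=float)
    cols["aromatic_atom_count"] = np.array(aromatic, dtype=float)
    M = rule_match_matrix(smiles, rule_table, label_names)
    for j, name in enumerate(label_names):
        cols[f"match_{name}"] = M[:, j].astype(float)

    n_structural = len(cols)
    n_noise = max(spec.n_descriptors - n_structural, 0)
    scales = np.exp(
        rng.uniform(np.log(spec.scale_range[0]), np.log(spec.scale_range[1]), size=n_noise)
    )
    for j in range(n_noise):
        cols[f"noise_{j:04d}"] = rng.normal(size=n) * scales[j]
    table = pd.DataFrame(cols)
    all_cols = list(table.columns)
    noise_cols = [c for c in all_cols if c.startswith("noise_")]

    # outliers: extreme multiplicative spikes in noise columns
    if spec.outlier_rate > 0 and noise_cols:
        block = table[noise_cols].to_numpy()
        mask = rng.random(block.shape) < spec.outlier_rate
        block[mask] = block[mask] * 100.0 + np.sign(block[mask] + 1e-12) * 10.0
        table[noise_cols] = block

    # tiered missingness: high-missing tier drawn from noise columns only
    f1, f2, f3 = spec.missing_tier_fractions
    n1 = int(round(f1 * len(all_cols)))
    n2 = int(round(f2 * len(all_cols)))
    n3 = min(int(round(f3 * len(all_cols))), len(noise_cols))
    t3 = list(rng.choice(noise_cols, size=n3, replace=False)) if n3 else []
    rest = [c for c in all_cols if c not in t3]
    picked = list(rng.choice(rest, size=min(n1 + n2, len(rest)), replace=False))
    t1, t2 = picked[:n1], picked[n1 : n1 + n2]
    for col, lo, hi in [(t1, 0.005, 0.05), (t2, 0.05, 0.30), (t3, 0.305, 0.50)]:
        for c in col:
            rate = rng.uniform(lo, hi)
            miss = rng.random(n) < rate
            vals = table[c].to_numpy(dtype=float)
            vals[miss] = np.nan
            table[c] = vals
    return table


def make_dataset(config: GenerationConfig, descriptor_spec: DescriptorNoiseSpec | None = None):
    """Generate molecules, planted labels and (optionally) descriptors."""
    smiles = generate_molecules(config)
    labels = plant_labels(smiles, config)
    table = None
    if descriptor_spec is not None:
        table = synth_descriptor_table(
            smiles, descriptor_spec, config.seed,
            rule_table=config.rule_table, label_names=config.label_names,
        )
    return smiles, labels, table


def write_dataset(outdir, smiles, labels: LabelMatrix, table: pd.DataFrame | None = None) -> None:
    """Write molecules.csv (smiles + labels) and descriptors.csv."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mols = pd.DataFrame({"smiles": smiles})
    mols = pd.concat([mols, labels.to_frame()], axis=1)
    mols.to_csv(outdir / "molecules.csv", index=False)
    if table is not None:
        table.to_csv(outdir / "descriptors.csv", index=False)
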