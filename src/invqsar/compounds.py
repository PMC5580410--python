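"""Compound curation, descriptor computation and descriptor constraints.

Activity curation follows standard ChEMBL-style practice: multiple Ki
measurements (nM) for a compound are merged by geometric mean provided they
all fall within one order of magnitude, and converted to pKi = 9 - log10(Ki
in nM).  Structures are standardized to their parent fragment and screened
against PAINS/reactive-substructure catalogs.  Descriptors are computed
with RDKit from a 44-name default registry (constitutional counts,
Chi/Kappa topological indices, Gasteiger partial-charge extrema), then
pruned by a greedy |r| > 0.9 correlation filter.

Count descriptors admit consistency constraints of the form
x_lesser <= x_greater (e.g. H-bond acceptors cannot exceed heavy atoms);
:func:`build_constraints` turns such rules into inequality functions for
the optimizer.

A synthetic fixture generator emulates a curated compound table: bounded
integer count descriptors with built-in consistency relations, continuous
descriptors, and a smooth planted activity surface with log-normal-style
potency noise on the pKi scale.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, FilterCatalog
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CompoundRecord:
    """One compound with its raw Ki measurements and curated potency."""

    compound_id: str
    smiles: str
    ki_values: list[float] = dataclasses.field(default_factory=list)
    pki: Optional[float] = None


@dataclasses.dataclass(frozen=True)
class ConstraintRule:
    """Descriptor-consistency relation: ``lesser <= greater`` in every
    physically possible compound."""

    lesser: str
    greater: str


@dataclasses.dataclass
class DescriptorTable:
    """Named numeric descriptor matrix with discreteness flags."""

    frame: pd.DataFrame
    discrete: pd.Series
    dropped: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("descriptor column names must be unique")
        if self.frame.isna().any().any():
            raise ValueError("descriptor table contains missing values")
        self.discrete = self.discrete.reindex(self.frame.columns).fillna(False).astype(bool)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def discrete_mask(self) -> np.ndarray:
        return self.discrete.to_numpy()

    def bounds(self) -> pd.DataFrame:
        return pd.DataFrame({"min": self.frame.min(), "max": self.frame.max()})

    def select(self, columns: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(
            frame=self.frame[list(columns)].copy(),
            discrete=self.discrete[list(columns)],
            dropped=list(self.dropped),
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="compound_id", float_format="%.6g")


# --- activity curation ------------------------------------------------------


def aggregate_activity(ki_values: Sequence[float]) -> Optional[float]:
    """Merge Ki measurements (nM) into a pKi, or discard.

    Measurements must agree within one order of magnitude (max/min < 10);
    the merged potency is the geometric mean, reported as
    pKi = 9 - log10(Ki nM).  Returns None for discarded compounds.
    """
    ki = np.asarray(list(ki_values), dtype=float)
    if ki.size == 0:
        raise ValueError("ki_values must be non-empty")
    if np.any(ki <= 0):
        raise ValueError("Ki values must be positive")
    if ki.max() / ki.min() >= 10.0:
        return None
    geo_mean = float(np.exp(np.mean(np.log(ki))))
    return 9.0 - math.log10(geo_mean)


def curate_records(records: Iterable[CompoundRecord]) -> list[CompoundRecord]:
    """Assign pKi to each record; drop records spanning >1 order of magnitude."""
    kept = []
    for rec in records:
        pki = aggregate_activity(rec.ki_values)
        if pki is not None:
            kept.append(dataclasses.replace(rec, pki=pki))
    return kept


# --- structure standardization and filtering --------------------------------


def default_filter_catalog() -> FilterCatalog.FilterCatalog:
    """PAINS plus Brenk reactive/unstable substructure alerts."""
    params = FilterCatalog.FilterCatalogParams()
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS)
    params.AddCatalog(FilterCatalog.FilterCatalogParams.FilterCatalogs.BRENK)
    return FilterCatalog.FilterCatalog(params)


def standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Strip salts/solvents to the parent fragment and normalize."""
    parent = rdMolStandardize.FragmentParent(mol)
    Chem.SanitizeMol(parent)  # FragmentParent leaves ring info uninitialized
    return parent


def structure_filter(
    records: Sequence[CompoundRecord],
    catalog: Optional[FilterCatalog.FilterCatalog] = None,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Drop unparsable structures and substructure-alert matches.

    Returns the kept records and a rejection log with columns
    ``compound_id`` and ``reason`` ("parse" or the name of the alert that
    fired).  Pass an empty ``FilterCatalog()`` to keep all parsable records.
    """
    if catalog is None:
        catalog = default_filter_catalog()
    kept: list[CompoundRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rejected.append((rec.compound_id, "parse"))
            continue
        mol = standardize_mol(mol)
        entry = catalog.GetFirstMatch(mol)
        if entry is not None:
            rejected.append((rec.compound_id, entry.GetDescription()))
            continue
        kept.append(rec)
    log = pd.DataFrame(rejected, columns=["compound_id", "reason"])
    return kept, log


# --- descriptor registry ----------------------------------------------------

# 44 RDKit descriptors: constitutional counts, Chi/Kappa topological indices
# and Gasteiger partial-charge extrema.  Count descriptors are discrete.
_COUNT_DESCRIPTORS = [
    "HeavyAtomCount",
    "NumRotatableBonds",
    "NumHAcceptors",
    "NumHDonors",
    "NumHeteroatoms",
    "RingCount",
    "NumAromaticRings",
    "NumAliphaticRings",
    "NumSaturatedRings",
    "NumAromaticHeterocycles",
    "NumAromaticCarbocycles",
    "NumAliphaticHeterocycles",
    "NumAliphaticCarbocycles",
    "NumSaturatedHeterocycles",
    "NumSaturatedCarbocycles",
    "NOCount",
    "NHOHCount",
    "NumValenceElectrons",
]
_CONTINUOUS_DESCRIPTORS = [
    "MolWt",
    "FractionCSP3",
    "TPSA",
    "LabuteASA",
    "MolLogP",
    "BalabanJ",
    "BertzCT",
    "HallKierAlpha",
    "Chi0",
    "Chi1",
    "Chi0n",
    "Chi1n",
    "Chi2n",
    "Chi3n",
    "Chi4n",
    "Chi0v",
    "Chi1v",
    "Chi2v",
    "Chi3v",
    "Chi4v",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    "MaxPartialCharge",
    "MinPartialCharge",
    "MaxAbsPartialCharge",
]
DEFAULT_DESCRIPTORS: list[str] = _COUNT_DESCRIPTORS + _CONTINUOUS_DESCRIPTORS

DEFAULT_CONSTRAINT_RULES: list[ConstraintRule] = [
    ConstraintRule("NumHAcceptors", "HeavyAtomCount"),
    ConstraintRule("NumHDonors", "HeavyAtomCount"),
    ConstraintRule("NumHeteroatoms", "HeavyAtomCount"),
    ConstraintRule("NumAromaticRings", "RingCount"),
    ConstraintRule("NumAliphaticRings", "RingCount"),
]


def compute_descriptor_table(
    records: Sequence[CompoundRecord],
    descriptor_names: Optional[Sequence[str]] = None,
) -> DescriptorTable:
    """Compute one descriptor row per compound.

    Unknown names raise; compounds whose computation fails (unparsable
    structure or NaN descriptor value) are dropped and listed in
    ``table.dropped``.
    """
    names = list(descriptor_names) if descriptor_names is not None else list(DEFAULT_DESCRIPTORS)
    fns: list[Callable] = []
    for name in names:
        fn = getattr(Descriptors, name, None)
        if fn is None:
            raise KeyError(f"unknown descriptor {name!r}")
        fns.append(fn)

    rows, ids, dropped = [], [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            dropped.append((rec.compound_id, "parse"))
            logger.warning("dropping %s: unparsable SMILES", rec.compound_id)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values = [float(fn(mol)) for fn in fns]
        except Exception as exc:  # pragma: no cover - rdkit internals
            dropped.append((rec.compound_id, f"descriptor: {exc}"))
            continue
        if not all(np.isfinite(values)):
            dropped.append((rec.compound_id, "non-finite descriptor"))
            logger.warning("dropping %s: non-finite descriptor value", rec.compound_id)
            continue
        rows.append(values)
        ids.append(rec.compound_id)

    frame = pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"), columns=names)
    discrete = pd.Series({n: n in set(_COUNT_DESCRIPTORS) for n in names})
    return DescriptorTable(frame=frame, discrete=discrete, dropped=dropped)


def correlation_filter(table: DescriptorTable, threshold: float = 0.9) -> DescriptorTable:
    """Greedy correlation-based variable selection.

    Columns are scanned in order; a column is dropped when its absolute
    Pearson correlation with any already-retained column exceeds the
    threshold.  Zero-variance columns correlate with nothing and are
    retained with a warning.
    """
    X = table.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        warnings.warn(
            "zero-variance column(s) retained: "
            f"{[c for c, s in zip(table.columns, stds) if s == 0]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    keep: list[int] = []
    for j in range(X.shape[1]):
        if all(abs(corr[j, k]) <= threshold for k in keep):
            keep.append(j)
    return table.select([table.columns[j] for j in keep])


def build_constraints(
    rules: Sequence[ConstraintRule], columns: Sequence[str]
) -> list[Callable[[np.ndarray], np.ndarray]]:
    """Turn consistency rules into inequality functions g(x) = x_lesser - x_greater.

    The returned callables act on (n, d) matrices in *unscaled* descriptor
    units, column order matching ``columns``; feasibility is g <= 0.
    """
    index = {name: j for j, name in enumerate(columns)}
    funcs = []
    for rule in rules:
        for name in (rule.lesser, rule.greater):
            if name not in index:
                raise KeyError(f"unknown descriptor {name!r} in constraint rule")
        jl, jg = index[rule.lesser], index[rule.greater]

        def g(X, jl=jl, jg=jg):
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return X[:, jl] - X[:, jg]

        funcs.append(g)
    return funcs


def applicable_rules(
    rules: Sequence[ConstraintRule], columns: Sequence[str]
) -> list[ConstraintRule]:
    """Subset of rules whose both descriptors survived variable selection."""
    cols = set(columns)
    return [r for r in rules if r.lesser in cols and r.greater in cols]


def split_train_test(items: Sequence, seed: int) -> tuple[list, list]:
    """Seeded random half split; odd counts give training the extra item."""
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = math.ceil(len(items) / 2)
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


# --- synthetic compound fixture ---------------------------------------------

FIXTURE_RULES: list[ConstraintRule] = [
    ConstraintRule("hba", "heavy_atoms"),
    ConstraintRule("hbd", "hba"),
    ConstraintRule("aromatic_rings", "rings"),
]

#: Planted activity optimum of the fixture, in descriptor units.
FIXTURE_OPTIMUM = {"logp": 2.0, "tpsa": 60.0, "heavy_atoms": 25.0}


def fixture_activity_surface(
    logp: np.ndarray, tpsa: np.ndarray, heavy: np.ndarray
) -> np.ndarray:
    """Noise-free planted pKi surface: a smooth unimodal bump over three
    planted descriptors, peaking at drug-like values (logP 2, TPSA 60,
    25 heavy atoms).  Length scales are broad relative to the descriptor
    ranges so the surface is recoverable by an RBF regression through the
    uninformative descriptors at the fixture's assay-noise level."""
    return (
        6.0
        + 3.0 * np.exp(-(((logp - 2.0) / 2.5) ** 2))
        + 2.25 * np.exp(-(((tpsa - 60.0) / 40.0) ** 2))
        + 1.5 * np.exp(-(((heavy - 25.0) / 12.0) ** 2))
    )


def generate_compound_fixture(
    n: int = 600, d: int = 15, seed: int = 0, noise_sigma: float = 0.3
) -> tuple[DescriptorTable, np.ndarray]:
    """Synthetic stand-in for a curated compound descriptor table.

    Emulates the statistical shape of a real compound set without any
    chemistry: integer count descriptors with built-in consistency
    relations (see :data:`FIXTURE_RULES`), correlated continuous
    descriptors, and a pKi formed by :func:`fixture_activity_surface` on
    three planted descriptors (logp, tpsa, heavy_atoms) plus N(0, σ²) noise
    with σ = 0.3 pKi units (multiplicative/log-normal noise on Ki).
    Columns beyond the 8 structured ones are uninformative uniform noise.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if d < 8:
        raise ValueError("d must be >= 8")
    rng = np.random.default_rng(seed)
    heavy = rng.integers(10, 41, size=n)
    hba = rng.binomial(heavy, 0.2)
    hbd = rng.binomial(hba, 0.5)
    rings = rng.integers(0, 5, size=n)
    aromatic = rng.binomial(rings, 0.7)
    mw = 13.0 * heavy + rng.normal(0.0, 8.0, size=n)
    logp = rng.uniform(-2.0, 5.0, size=n)
    tpsa = np.clip(20.0 * hba + 5.0 * hbd + rng.normal(0.0, 10.0, size=n), 0.0, None)

    data = {
        "heavy_atoms": heavy.astype(float),
        "hba": hba.astype(float),
        "hbd": hbd.astype(float),
        "rings": rings.astype(float),
        "aromatic_rings": aromatic.astype(float),
        "mw": mw,
        "logp": logp,
        "tpsa": tpsa,
    }
    for j in range(8, d):
        data[f"noise_{j:02d}"] = rng.uniform(-1.0, 1.0, size=n)
    frame = pd.DataFrame(
        data, index=pd.Index([f"CPD{i:05d}" for i in range(n)], name="compound_id")
    )
    discrete = pd.Series(
        {c: c in {"heavy_atoms", "hba", "hbd", "rings", "aromatic_rings"} for c in frame.columns}
    )
    pki = fixture_activity_surface(logp, tpsa, heavy.astype(float)) + rng.normal(
        0.0, noise_sigma, size=n
    )
    return DescriptorTable(frame=frame, discrete=discrete), pki


# --- file I/O ---------------------------------------------------------------


def read_activity_csv(path) -> list[CompoundRecord]:
    """Read an activity table (compound_id, smiles, ki_nM) into records.

    ``ki_nM`` may hold several ';'-separated measurements.
    """
    frame = pd.read_csv(path)
    required = {"compound_id", "smiles", "ki_nM"}
    if not required.issubset(frame.columns):
        raise ValueError(f"activity CSV must have columns {sorted(required)}")
    records = []
    for _, row in frame.iterrows():
        kis = [float(v) for v in str(row["ki_nM"]).split(";") if v.strip()]
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                smiles=str(row["smiles"]),
                ki_values=kis,
            )
        )
    return records


def read_smiles_file(path) -> list[CompoundRecord]:
    """Read an id-TAB-smiles (.smi) file; lines 'smiles<TAB>id' also accepted."""
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            first, second = parts[0], parts[1]
            # Heuristic: the SMILES field is the one RDKit parses.
            if Chem.MolFromSmiles(first) is None and Chem.MolFromSmiles(second) is not None:
                cid, smi = first, second
            else:
                smi, cid = first, second
            records.append(CompoundRecord(compound_id=cid, smiles=smi))
    return records
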