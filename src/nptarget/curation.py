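"""Bioactivity curation: raw activity records -> clean binary label matrices.

The pipeline turns a ChEMBL-style activity export (compound_id, SMILES,
target_id, activity_type, standard value in nM) plus a natural-product
structure list into two aligned compound x target binary matrices: a large
pre-training matrix and a smaller natural-product fine-tuning matrix.

Rules, in order:

1. structures are sanitized (largest fragment, charges neutralized,
   stereochemistry erased) and canonicalized;
2. structures with elements outside {H, C, N, O, P, S, F, Cl, Br} are removed;
3. multiple measurements for one compound-target pair are averaged
   (arithmetic mean on the nM scale);
4. a pair is active iff its mean value is strictly below 1000 nM;
5. distinct input compounds that collapse to the same canonical structure
   are merged when their active-target sets agree and removed entirely when
   they disagree;
6. all-zero rows and all-zero columns are pruned to a fixpoint;
7. rows whose canonical structure appears in the natural-product list are
   split off into the fine-tuning matrix;
8. natural-product targets with fewer than ``min_active`` active compounds
   are dropped; compounds active only on dropped targets are retained as
   all-zero rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ALLOWED_ATOMIC_NUMBERS = frozenset({1, 6, 7, 8, 15, 16, 9, 17, 35})
ALLOWED_ACTIVITY_TYPES = frozenset({"IC50", "EC50", "Ki", "Kd"})
ACTIVITY_THRESHOLD_NM = 1000.0

_UNCHARGER = rdMolStandardize.Uncharger()


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the offender."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


@dataclass(frozen=True)
class SanitizedCompound:
    """A canonicalized structure and the raw compound ids that map to it."""

    canonical_smiles: str
    source_ids: frozenset = frozenset()


@dataclass
class LabelMatrix:
    """Binary compounds x targets activity matrix with aligned indexes."""

    compounds: list  # list[SanitizedCompound]
    targets: list  # list[str]
    labels: np.ndarray  # int8, shape (n_compounds, n_targets)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.compounds), len(self.targets)):
            raise ValueError(
                f"label shape {self.labels.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.targets)} targets"
            )
        smiles = [c.canonical_smiles for c in self.compounds]
        if len(set(smiles)) != len(smiles):
            raise ValueError("duplicate canonical SMILES rows")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate target ids")

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def smiles(self) -> list:
        return [c.canonical_smiles for c in self.compounds]

    def to_dir(self, out_dir) -> None:
        """Serialize as compounds.csv + targets.csv + labels.mtx."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "index": range(self.n_compounds),
                "canonical_smiles": self.smiles,
                "source_ids": [
                    ";".join(sorted(c.source_ids)) for c in self.compounds
                ],
            }
        ).to_csv(out / "compounds.csv", index=False)
        pd.DataFrame(
            {"index": range(self.n_targets), "target_id": self.targets}
        ).to_csv(out / "targets.csv", index=False)
        scipy_io.mmwrite(
            str(out / "labels.mtx"), sparse.coo_matrix(self.labels)
        )

    @classmethod
    def from_dir(cls, in_dir) -> "LabelMatrix":
        src = Path(in_dir)
        comp = pd.read_csv(src / "compounds.csv", keep_default_na=False)
        targ = pd.read_csv(src / "targets.csv", keep_default_na=False)
        labels = np.asarray(
            scipy_io.mmread(str(src / "labels.mtx")).todense(), dtype=np.int8
        )
        compounds = [
            SanitizedCompound(
                row.canonical_smiles,
                frozenset(s for s in str(row.source_ids).split(";") if s),
            )
            for row in comp.itertuples()
        ]
        return cls(compounds, list(targ["target_id"].astype(str)), labels)


@dataclass
class CurationReport:
    """Per-rule removal counts; survivors + removals add up to the input."""

    input_records: int = 0
    invalid_records: int = 0  # bad activity type / nonpositive value
    unparsable_records: int = 0
    element_filter_records: int = 0
    surviving_records: int = 0
    conflict_structures_removed: int = 0
    pruned_rows: int = 0
    pruned_targets: int = 0
    uncharged_failures: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ---------------------------------------------------------------------------
# structure sanitization
# ---------------------------------------------------------------------------

def sanitize_structure(smiles: str) -> SanitizedCompound:
    """Canonicalize: keep the largest fragment, neutralize, drop stereo.

    The largest fragment is the one with the most heavy atoms; ties break by
    molecular weight, then by lexicographically smallest canonical SMILES.
    Sites that cannot be neutralized (e.g. quaternary nitrogen) survive
    as-is. Deterministic and idempotent.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    best = max(
        frags,
        key=lambda f: (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            # negated lexicographic rank: max() must prefer the smallest
            [-ord(ch) for ch in Chem.MolToSmiles(f)],
        ),
    )
    best = _UNCHARGER.uncharge(best)
    Chem.RemoveStereochemistry(best)
    return SanitizedCompound(Chem.MolToSmiles(best))


def passes_element_filter(compound: SanitizedCompound) -> bool:
    """True iff every atom is in {H, C, N, O, P, S, F, Cl, Br}."""
    mol = Chem.MolFromSmiles(compound.canonical_smiles)
    if mol is None:  # canonical SMILES always reparses; defensive
        raise SmilesParseError(compound.canonical_smiles)
    return all(
        a.GetAtomicNum() in ALLOWED_ATOMIC_NUMBERS for a in mol.GetAtoms()
    )


# ---------------------------------------------------------------------------
# activity aggregation and binarization
# ---------------------------------------------------------------------------

def aggregate_activity(values_nM: Sequence[float], geometric: bool = False) -> float:
    """Mean activity over repeated measurements of one compound-target pair.

    Arithmetic mean on the nM scale by default; ``geometric=True`` switches
    to the geometric mean (log-scale averaging).
    """
    vals = np.asarray(list(values_nM), dtype=float)
    if vals.size == 0:
        raise ValueError("aggregate_activity requires at least one value")
    if np.any(vals <= 0):
        raise ValueError("activity values must be positive")
    if geometric:
        return float(np.exp(np.mean(np.log(vals))))
    return float(vals.mean())


def binarize_activity(mean_value_nM: float) -> int:
    """1 iff the mean value is strictly below 1000 nM; 1000 itself is 0."""
    if mean_value_nM <= 0:
        raise ValueError("activity value must be positive")
    return int(mean_value_nM < ACTIVITY_THRESHOLD_NM)


# ---------------------------------------------------------------------------
# matrix-level rules
# ---------------------------------------------------------------------------

def resolve_conflicts(
    rows: Sequence[tuple], targets: Sequence[str]
) -> tuple[LabelMatrix, int]:
    """Merge or drop rows that share a canonical structure.

    ``rows`` is a sequence of (SanitizedCompound, binary label vector)
    aligned to ``targets``.  Rows with the same canonical SMILES merge into
    one (union of source ids) when their active-target sets agree, and are
    all removed when they disagree.  Returns the matrix and the number of
    canonical structures removed by conflicts.  Output row order follows
    first appearance of each surviving structure, so the result is invariant
    to input order up to relabeling.
    """
    by_smiles: dict[str, list[tuple]] = {}
    order: list[str] = []
    for comp, vec in rows:
        key = comp.canonical_smiles
        if key not in by_smiles:
            by_smiles[key] = []
            order.append(key)
        by_smiles[key].append((comp, np.asarray(vec, dtype=np.int8)))

    kept_compounds: list[SanitizedCompound] = []
    kept_rows: list[np.ndarray] = []
    n_conflicts = 0
    for key in order:
        group = by_smiles[key]
        active_sets = {tuple(np.flatnonzero(vec)) for _, vec in group}
        if len(active_sets) > 1:
            n_conflicts += 1
            continue
        ids = frozenset().union(*(c.source_ids for c, _ in group))
        kept_compounds.append(SanitizedCompound(key, ids))
        kept_rows.append(group[0][1])

    labels = (
        np.vstack(kept_rows)
        if kept_rows
        else np.zeros((0, len(targets)), dtype=np.int8)
    )
    return LabelMatrix(kept_compounds, list(targets), labels), n_conflicts


def prune_matrix(matrix: LabelMatrix) -> tuple[LabelMatrix, int, int]:
    """Drop all-zero rows and columns until a fixpoint.

    Removing a column can zero out a row (and vice versa), so the scan
    repeats until nothing changes; the fixpoint is independent of sweep
    order.  Returns (pruned matrix, rows removed, columns removed).
    """
    labels = matrix.labels
    row_keep = np.ones(labels.shape[0], dtype=bool)
    col_keep = np.ones(labels.shape[1], dtype=bool)
    while True:
        sub = labels[np.ix_(row_keep, col_keep)]
        new_rows = sub.sum(axis=1) > 0
        new_cols = sub.sum(axis=0) > 0
        if new_rows.all() and new_cols.all():
            break
        row_keep[np.flatnonzero(row_keep)[~new_rows]] = False
        col_keep[np.flatnonzero(col_keep)[~new_cols]] = False
    pruned = LabelMatrix(
        [c for c, k in zip(matrix.compounds, row_keep) if k],
        [t for t, k in zip(matrix.targets, col_keep) if k],
        labels[np.ix_(row_keep, col_keep)],
    )
    return pruned, int((~row_keep).sum()), int((~col_keep).sum())


def partition_by_structure_set(
    matrix: LabelMatrix, np_structures: Iterable[str]
) -> tuple[LabelMatrix, LabelMatrix]:
    """Split rows into (pre-training matrix, natural-product matrix).

    ``np_structures`` must already be canonical (same sanitizer).  Rows whose
    canonical SMILES belongs to the set form the natural-product matrix; the
    rest form the pre-training matrix.
    """
    np_set = set(np_structures)
    in_np = np.array(
        [c.canonical_smiles in np_set for c in matrix.compounds], dtype=bool
    )
    def take(mask):
        return LabelMatrix(
            [c for c, k in zip(matrix.compounds, mask) if k],
            list(matrix.targets),
            matrix.labels[mask],
        )
    return take(~in_np), take(in_np)


def select_high_frequency_targets(
    np_matrix: LabelMatrix, min_active: int = 10
) -> LabelMatrix:
    """Keep targets with >= ``min_active`` active natural products.

    Compounds active only on dropped low-frequency targets are retained as
    all-zero rows: they still contribute inactive labels during training.
    """
    if min_active < 1:
        raise ValueError("min_active must be >= 1")
    keep = np_matrix.labels.sum(axis=0) >= min_active
    return LabelMatrix(
        list(np_matrix.compounds),
        [t for t, k in zip(np_matrix.targets, keep) if k],
        np_matrix.labels[:, keep],
    )


def restrict_targets(matrix: LabelMatrix, targets: Sequence[str]) -> LabelMatrix:
    """Project a matrix onto a given target list (rows retained, even if zero)."""
    idx = {t: j for j, t in enumerate(matrix.targets)}
    missing = [t for t in targets if t not in idx]
    if missing:
        raise ValueError(f"targets not in matrix: {missing}")
    cols = [idx[t] for t in targets]
    return LabelMatrix(
        list(matrix.compounds), list(targets), matrix.labels[:, cols]
    )


# ---------------------------------------------------------------------------
# end-to-end curation
# ---------------------------------------------------------------------------

def sanitize_structure_list(smiles_list: Iterable[str]) -> set:
    """Canonicalize a natural-product structure list with the same rules.

    Unparsable or element-filtered structures are silently dropped (they
    cannot match any curated row anyway).
    """
    out = set()
    for smi in smiles_list:
        try:
            comp = sanitize_structure(smi)
        except SmilesParseError:
            continue
        if passes_element_filter(comp):
            out.add(comp.canonical_smiles)
    return out


def curate(
    activities: pd.DataFrame,
    np_structures: Iterable[str],
    min_active: int = 10,
    geometric_mean: bool = False,
) -> tuple[LabelMatrix, LabelMatrix, CurationReport]:
    """Run the full curation pipeline.

    ``activities`` needs columns compound_id, smiles, target_id,
    activity_type, value_nM. ``np_structures`` is an iterable of raw SMILES
    defining the natural-product set (sanitized here with the same rules).
    Returns (pretrain matrix, natural-product matrix, report); both matrices
    share the natural-product high-frequency target columns.
    """
    report = CurationReport(input_records=len(activities))
    df = activities.copy()
    df.columns = [c.lower() for c in df.columns]
    required = {"compound_id", "smiles", "target_id", "activity_type", "value_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table must have columns {sorted(required)}")

    valid = (
        df["activity_type"].isin(ALLOWED_ACTIVITY_TYPES)
        & (pd.to_numeric(df["value_nm"], errors="coerce") > 0)
    )
    report.invalid_records = int((~valid).sum())
    df = df[valid]

    # sanitize each distinct raw SMILES once
    canon: dict[str, str | None] = {}
    ok_elements: dict[str, bool] = {}
    for smi in df["smiles"].unique():
        try:
            comp = sanitize_structure(smi)
        except SmilesParseError:
            canon[smi] = None
            continue
        canon[smi] = comp.canonical_smiles
        ok_elements[smi] = passes_element_filter(comp)

    parsable = df["smiles"].map(lambda s: canon[s] is not None)
    report.unparsable_records = int((~parsable).sum())
    df = df[parsable]
    elem_ok = df["smiles"].map(lambda s: ok_elements[s])
    report.element_filter_records = int((~elem_ok).sum())
    df = df[elem_ok]
    report.surviving_records = len(df)

    df = df.assign(canonical_smiles=df["smiles"].map(canon))

    # average repeated measurements per raw compound, then binarize
    agg = (
        df.groupby(["compound_id", "canonical_smiles", "target_id"])["value_nm"]
        .apply(lambda v: aggregate_activity(v, geometric=geometric_mean))
        .reset_index(name="mean_value_nm")
    )
    agg["active"] = agg["mean_value_nm"].map(binarize_activity)

    targets = sorted(agg["target_id"].astype(str).unique())
    t_index = {t: j for j, t in enumerate(targets)}
    rows = []
    for (cid, smi), grp in agg.groupby(["compound_id", "canonical_smiles"], sort=True):
        vec = np.zeros(len(targets), dtype=np.int8)
        for t, a in zip(grp["target_id"].astype(str), grp["active"]):
            vec[t_index[t]] = max(vec[t_index[t]], a)
        rows.append((SanitizedCompound(smi, frozenset({str(cid)})), vec))

    matrix, n_conflicts = resolve_conflicts(rows, targets)
    report.conflict_structures_removed = n_conflicts

    matrix, n_rows, n_cols = prune_matrix(matrix)
    report.pruned_rows = n_rows
    report.pruned_targets = n_cols

    np_set = sanitize_structure_list(np_structures)
    pretrain, np_matrix = partition_by_structure_set(matrix, np_set)
    np_matrix = select_high_frequency_targets(np_matrix, min_active=min_active)
    pretrain = restrict_targets(pretrain, np_matrix.targets)
    return pretrain, np_matrix, report
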