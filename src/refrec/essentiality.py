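"""Essentiality scoring from knockout feasibility profiles.

The substrate of this stage is a binary feasibility matrix: one row per
knockout experiment, one column per network object (or merged variable),
``True`` meaning the object stayed feasible under that knockout.  Objects
that are blocked and unblocked by exactly the same experiments carry no
independent information, so they are merged into a single variable before
scoring — a purely structural reduction that never consults phenotypes.

The essentiality score of a variable is the fraction of inviable strains
among all experimental strains whose damage blocks it, i.e. the empirical
probability of an inviable phenotype given the variable was infeasible.
A score of one with enough supporting experiments defines an
*unconditionally essential* object.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

VIABLE = "viable"
INVIABLE = "inviable"


class PhenotypeMismatchError(ValueError):
    """Rows of the matrix and the phenotype table do not correspond."""


@dataclass(frozen=True)
class KnockoutExperiment:
    """A mutant strain: 1-3 knocked genes and an experimental phenotype.

    Viable covers both normal and slow-growing strains; the label is
    strictly binary.
    """

    strain_id: str
    genes: tuple
    phenotype: str

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if not 1 <= len(self.genes) <= 3:
            raise ValueError(
                f"{self.strain_id}: expected 1-3 knocked genes, "
                f"got {len(self.genes)}")
        if self.phenotype not in (VIABLE, INVIABLE):
            raise ValueError(
                f"{self.strain_id}: phenotype must be "
                f"'{VIABLE}' or '{INVIABLE}'")


@dataclass
class FeasibilityMatrix:
    """Knockouts x variables binary matrix with merged-variable groups.

    ``values[i, j]`` is ``True`` when variable ``j`` stayed feasible under
    experiment ``i``.  ``groups`` maps each variable id to the tuple of
    original object ids it stands for (singletons before merging).
    """

    row_ids: list
    column_ids: list
    values: np.ndarray
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.row_ids), len(self.column_ids)):
            raise ValueError("matrix shape does not match row/column ids")
        if not self.groups:
            self.groups = {c: (c,) for c in self.column_ids}

    @property
    def n_experiments(self) -> int:
        return len(self.row_ids)

    def column_index(self):
        return {c: j for j, c in enumerate(self.column_ids)}

    def expand(self) -> "FeasibilityMatrix":
        """Reconstruct the full (unmerged) matrix from the groups."""
        cols, take = [], []
        for j, var in enumerate(self.column_ids):
            for member in self.groups[var]:
                cols.append(member)
                take.append(j)
        return FeasibilityMatrix(
            row_ids=list(self.row_ids), column_ids=cols,
            values=self.values[:, take],
            groups={c: (c,) for c in cols})

    # -- persistence (sparse coordinate format + label sidecars) ----------
    def save(self, prefix):
        """Write ``<prefix>.mtx`` (blocked entries) plus row/column/group
        sidecar files."""
        prefix = Path(prefix)
        blocked = scipy.sparse.coo_matrix(~self.values)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), blocked)
        prefix.with_suffix(".rows.txt").write_text(
            "\n".join(self.row_ids) + "\n")
        prefix.with_suffix(".cols.txt").write_text(
            "\n".join(self.column_ids) + "\n")
        with open(prefix.with_suffix(".groups.tsv"), "w") as fh:
            for var in self.column_ids:
                fh.write(f"{var}\t{';'.join(self.groups[var])}\n")

    @classmethod
    def load(cls, prefix) -> "FeasibilityMatrix":
        prefix = Path(prefix)
        blocked = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
        rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
        cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
        groups = {}
        for line in prefix.with_suffix(".groups.tsv").read_text().splitlines():
            var, _, members = line.partition("\t")
            groups[var] = tuple(members.split(";"))
        return cls(rows, cols, ~blocked.astype(bool), groups)


def merge_identical_variables(matrix: FeasibilityMatrix) -> FeasibilityMatrix:
    """Merge variables with identical feasibility across all experiments.

    Variables (columns) that agree on every knockout are indistinguishable
    to any downstream analysis, so they are collapsed into one variable
    whose group records the partition.  On central-dogma chains this
    typically merges a gene with its transcription, transcript,
    translation and protein.  Phenotype information is never consulted.
    """
    first_of_pattern: dict[bytes, int] = {}
    new_ids, new_groups, take = [], {}, []
    members: dict[int, list] = {}
    cols = matrix.values.T.copy()  # contiguous per-column bytes
    for j, var in enumerate(matrix.column_ids):
        key = cols[j].tobytes()
        if key not in first_of_pattern:
            first_of_pattern[key] = j
            take.append(j)
            new_ids.append(var)
            members[j] = []
        members[first_of_pattern[key]].extend(matrix.groups[var])
    for j, var in zip(take, new_ids):
        new_groups[var] = tuple(members[j])
    return FeasibilityMatrix(
        row_ids=list(matrix.row_ids), column_ids=new_ids,
        values=matrix.values[:, take], groups=new_groups)


def _phenotype_vector(matrix, phenotypes):
    """Align phenotypes to matrix rows; returns a boolean inviable mask."""
    if isinstance(phenotypes, dict):
        lookup = phenotypes
    else:
        lookup = {e.strain_id: e.phenotype for e in phenotypes}
    missing = [r for r in matrix.row_ids if r not in lookup]
    if missing:
        raise PhenotypeMismatchError(
            f"no phenotype for rows {missing[:3]}"
            + ("..." if len(missing) > 3 else ""))
    return np.array([lookup[r] == INVIABLE for r in matrix.row_ids])


def essentiality_scores(matrix: FeasibilityMatrix, phenotypes) -> pd.DataFrame:
    """Compute per-variable essentiality scores.

    Returns a DataFrame indexed by variable id with columns
    ``n_blocking`` (experiments with the variable infeasible),
    ``n_lethal_blocking`` (those with inviable phenotype) and ``score`` =
    ``n_lethal_blocking / n_blocking``.  Variables never blocked get a
    missing (NaN) score — never zero, which would falsely assert evidence
    of dispensability.

    ``phenotypes`` may be a list of :class:`KnockoutExperiment` or a
    mapping ``strain_id -> phenotype``.
    """
    inviable = _phenotype_vector(matrix, phenotypes)
    blocked = ~matrix.values
    n_blocking = blocked.sum(axis=0)
    n_lethal = blocked[inviable].sum(axis=0)
    with np.errstate(invalid="ignore"):
        score = np.where(n_blocking > 0, n_lethal / np.maximum(n_blocking, 1),
                         np.nan)
    return pd.DataFrame(
        {"n_blocking": n_blocking, "n_lethal_blocking": n_lethal,
         "score": score},
        index=pd.Index(matrix.column_ids, name="variable"))


def unconditionally_essential(records: pd.DataFrame, min_support: int = 1):
    """Variables with essentiality score exactly one.

    ``min_support`` filters on ``n_blocking``: the fewer knockouts block an
    object the more biased its score may be, so callers can require more
    evidence.  The default of 1 applies no extra filter beyond the score.
    """
    mask = (records["score"] == 1.0) & (records["n_blocking"] >= min_support)
    return list(records.index[mask])


def resolve_phenotype_conflicts(experiments):
    """Deduplicate experiments sharing a strain id by majority vote.

    Conflicting labels for the same strain are resolved by majority;
    ties keep the viable label and emit a warning (inviable evidence is
    discarded rather than inventing lethality).
    """
    by_strain: dict[str, list] = {}
    order = []
    for e in experiments:
        if e.strain_id not in by_strain:
            order.append(e.strain_id)
        by_strain[e.strain_id] = by_strain.get(e.strain_id, []) + [e]
    out = []
    for sid in order:
        group = by_strain[sid]
        counts = Counter(e.phenotype for e in group)
        if counts[VIABLE] == counts[INVIABLE] and counts[INVIABLE] > 0:
            warnings.warn(
                f"strain {sid!r}: tied phenotype labels, keeping viable",
                stacklevel=2)
            label = VIABLE
        else:
            label = counts.most_common(1)[0][0]
        out.append(KnockoutExperiment(sid, group[0].genes, label))
    return out


def read_experiment_table(path) -> list:
    """TSV columns: strain_id, genes (comma-separated), phenotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [KnockoutExperiment(r.strain_id, tuple(str(r.genes).split(",")),
                               r.phenotype)
            for r in df.itertuples(index=False)]


def write_experiment_table(experiments, path):
    with open(path, "w") as fh:
        fh.write("strain_id\tgenes\tphenotype\n")
        for e in experiments:
            fh.write(f"{e.strain_id}\t{','.join(e.genes)}\t{e.phenotype}\n")


def write_score_table(records: pd.DataFrame, groups: dict, path):
    """Scores as TSV: variable, group members, counts, score."""
    with open(path, "w") as fh:
        fh.write("variable\tmembers\tn_blocking\tn_lethal_blocking\tscore\n")
        for var, row in records.iterrows():
            score = "" if np.isnan(row["score"]) else f"{row['score']:.6g}"
            fh.write(f"{var}\t{';'.join(groups.get(var, (var,)))}\t"
                     f"{int(row['n_blocking'])}\t"
                     f"{int(row['n_lethal_blocking'])}\t{score}\n")
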