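"""Domain types and I/O for branch-level xylem conduit measurements.

The atom of every analysis in this package is a :class:`BranchRecord`: one
sampled terminal branch with counts of functional (dye-stained) conduits and
mean lumen diameters at its basal and apical cross-sections, plus the path
distance from the shoot apex to each section.  A :class:`Dataset` is an
ordered collection of such records; a :class:`Phylogeny` wraps an ultrametric
Newick chronogram used by the phylogenetic regression.

Canonical units are micrometres for conduit diameters and centimetres for
all path lengths.  Input tables in other units are converted at load time.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "BranchRecord",
    "Dataset",
    "Phylogeny",
    "ValidationIssue",
    "ValidationReport",
    "read_branch_table",
    "write_table",
    "read_newick",
    "validate",
    "CANONICAL_COLUMNS",
    "normalize_species_name",
]

#: Canonical column order for the on-disk CSV representation.
CANONICAL_COLUMNS = (
    "species_id",
    "n_base",
    "n_tip",
    "d_base_um",
    "d_tip_um",
    "dist_base_cm",
    "dist_tip_cm",
    "branched",
)

#: Multiplicative factors converting a supported input unit to the canonical
#: one (cm for distances, um for diameters).
_LENGTH_FACTORS = {"cm": 1.0, "m": 100.0, "mm": 0.1}
_DIAMETER_FACTORS = {"um": 1.0, "mm": 1000.0, "cm": 10000.0}


def normalize_species_name(name: str) -> str:
    """Normalize a species label for matching against tree tip labels.

    Trims surrounding whitespace, collapses internal whitespace runs and
    treats spaces and underscores as equivalent (Newick convention).
    """
    return "_".join(str(name).strip().split()).replace(" ", "_")


@dataclass(frozen=True)
class BranchRecord:
    """One sampled branch: conduit counts, diameters and apex distances.

    Parameters
    ----------
    species_id
        Species label (one branch per species in the reference design).
    n_base, n_tip
        Number of functional conduits in the basal and apical cross-section.
        For branched stems ``n_tip`` is the sum over all daughter twigs.
    d_base_um, d_tip_um
        Mean lumen diameter (um) at base and tip, each averaged over the
        measured conduits of that section.
    dist_base_cm, dist_tip_cm
        Path distance (cm) from the shoot apex to the basal and apical
        section.  The base is farther from the apex, so
        ``dist_base_cm > dist_tip_cm``.
    branched
        True when ``n_tip`` was obtained by summing daughter twigs.
    """

    species_id: str
    n_base: int
    n_tip: int
    d_base_um: float
    d_tip_um: float
    dist_base_cm: float
    dist_tip_cm: float
    branched: bool = False

    @property
    def segment_length_cm(self) -> float:
        """Length of the sampled segment, base section to tip section (cm)."""
        return self.dist_base_cm - self.dist_tip_cm

    @property
    def diameter_ratio(self) -> float:
        """R = d_base / d_tip, equal to the basal-to-apical radius ratio."""
        return self.d_base_um / self.d_tip_um

    def issues(self) -> list["ValidationIssue"]:
        """Invariant violations for this record (empty when fully valid)."""
        out: list[ValidationIssue] = []

        def err(f, msg):
            out.append(ValidationIssue(self.species_id, f, "ERROR", msg))

        def warn(f, msg):
            out.append(ValidationIssue(self.species_id, f, "WARNING", msg))

        if not self.n_base >= 1:
            err("n_base", f"conduit count must be >= 1, got {self.n_base}")
        if not self.n_tip >= 1:
            err("n_tip", f"conduit count must be >= 1, got {self.n_tip}")
        for f in ("d_base_um", "d_tip_um"):
            v = getattr(self, f)
            if not (math.isfinite(v) and v > 0):
                err(f, f"diameter must be positive and finite, got {v}")
        if not (math.isfinite(self.dist_tip_cm) and self.dist_tip_cm > 0):
            err("dist_tip_cm", f"apex distance must be > 0, got {self.dist_tip_cm}")
        if not (
            math.isfinite(self.dist_base_cm)
            and self.dist_base_cm > self.dist_tip_cm
        ):
            err(
                "dist_base_cm",
                "base must lie farther from the apex than the tip "
                f"(dist_base={self.dist_base_cm}, dist_tip={self.dist_tip_cm})",
            )
        # Tip-to-base widening is the empirical expectation, not a law:
        # a narrower base is suspicious but representable.
        if (
            self.d_base_um > 0
            and self.d_tip_um > 0
            and self.d_base_um < self.d_tip_um
        ):
            warn(
                "d_base_um",
                "d_base < d_tip: no tip-to-base widening on this branch "
                f"({self.d_base_um} < {self.d_tip_um})",
            )
        return out


@dataclass(frozen=True)
class ValidationIssue:
    record_id: str
    field: str
    level: str  # "ERROR" or "WARNING"
    message: str


@dataclass
class ValidationReport:
    """Structured list of per-record problems; serializes to JSON."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "ERROR"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "WARNING"]

    def __len__(self) -> int:
        return len(self.issues)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "record": i.record_id,
                    "field": i.field,
                    "level": i.level,
                    "message": i.message,
                }
                for i in self.issues
            ],
            indent=2,
        )


@dataclass
class Dataset:
    """Ordered collection of :class:`BranchRecord` with a provenance tag."""

    records: list[BranchRecord] = field(default_factory=list)
    provenance: str = ""
    #: issues raised while loading (skipped rows etc.); empty for built data
    load_report: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i) -> BranchRecord:
        return self.records[i]

    @property
    def species(self) -> list[str]:
        return [r.species_id for r in self.records]

    @property
    def n_species(self) -> int:
        """Number of unique species labels in the dataset."""
        return len(set(self.species))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with canonical columns plus derived quantities."""
        df = pd.DataFrame(
            [
                {c: getattr(r, c) for c in CANONICAL_COLUMNS}
                for r in self.records
            ],
            columns=list(CANONICAL_COLUMNS),
        )
        if len(df):
            df["segment_length_cm"] = df.dist_base_cm - df.dist_tip_cm
        else:
            df["segment_length_cm"] = pd.Series(dtype=float)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "Dataset":
        records = [
            BranchRecord(
                species_id=str(row.species_id),
                n_base=int(row.n_base),
                n_tip=int(row.n_tip),
                d_base_um=float(row.d_base_um),
                d_tip_um=float(row.d_tip_um),
                dist_base_cm=float(row.dist_base_cm),
                dist_tip_cm=float(row.dist_tip_cm),
                branched=bool(getattr(row, "branched", False)),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, provenance=provenance)


def validate(dataset: Dataset) -> ValidationReport:
    """Check every record's invariants; never mutates the data.

    Duplicate species labels are reported as errors unless the duplicated
    records are flagged ``branched`` (branched replicates are allowed).
    """
    report = ValidationReport()
    for rec in dataset:
        report.issues.extend(rec.issues())
    seen: dict[str, BranchRecord] = {}
    for rec in dataset:
        if rec.species_id in seen:
            if not (rec.branched or seen[rec.species_id].branched):
                report.issues.append(
                    ValidationIssue(
                        rec.species_id,
                        "species_id",
                        "ERROR",
                        "duplicate species label without branched flag",
                    )
                )
        else:
            seen[rec.species_id] = rec
    return report


def _coerce_row(
    rownum: int,
    raw: dict,
    units: dict,
    daughter_cols: list[str],
    tip_offset_cm: float,
    report: ValidationReport,
) -> BranchRecord | None:
    """Build one record from a mapped row; on failure log and return None."""
    rid = str(raw.get("species_id", f"row{rownum}"))
    try:
        dist_factor = _LENGTH_FACTORS[units.get("length", "cm")]
        diam_factor = _DIAMETER_FACTORS[units.get("diameter", "um")]
        if daughter_cols:
            n_tip = int(round(sum(float(raw[c]) for c in daughter_cols)))
            branched = True
        else:
            n_tip = int(round(float(raw["n_tip"])))
            branched = bool(raw.get("branched", False))
        if "dist_base_cm" in raw and not pd.isna(raw.get("dist_base_cm")):
            dist_base = float(raw["dist_base_cm"]) * dist_factor
            dist_tip = float(raw["dist_tip_cm"]) * dist_factor
        else:
            # Table provides only total branch length: take it as the apex
            # distance of the base and place the tip section at a fixed
            # leafy-tip offset.  Loudly approximate.
            dist_base = float(raw["total_length_cm"]) * dist_factor
            dist_tip = tip_offset_cm
            report.issues.append(
                ValidationIssue(
                    rid,
                    "dist_tip_cm",
                    "WARNING",
                    "only total branch length provided; dist_tip set to "
                    f"{tip_offset_cm} cm leafy-tip offset",
                )
            )
        rec = BranchRecord(
            species_id=rid,
            n_base=int(round(float(raw["n_base"]))),
            n_tip=n_tip,
            d_base_um=float(raw["d_base_um"]) * diam_factor,
            d_tip_um=float(raw["d_tip_um"]) * diam_factor,
            dist_base_cm=dist_base,
            dist_tip_cm=dist_tip,
            branched=branched,
        )
    except (KeyError, TypeError, ValueError) as exc:
        report.issues.append(
            ValidationIssue(
                rid, "row", "ERROR", f"row {rownum}: cannot coerce ({exc})"
            )
        )
        return None
    hard = [i for i in rec.issues() if i.level == "ERROR"]
    if hard:
        for issue in hard:
            report.issues.append(
                ValidationIssue(
                    rid, issue.field, "ERROR", f"row {rownum}: {issue.message}"
                )
            )
        return None
    return rec


def read_branch_table(
    path,
    column_map: dict | None = None,
    units: dict | None = None,
    daughter_columns: list[str] | None = None,
    tip_offset_cm: float = 10.0,
    provenance: str | None = None,
) -> Dataset:
    """Read a delimited branch-measurement table into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Mapping from canonical field names (``species_id``, ``n_base``,
        ``n_tip``, ``d_base_um``, ``d_tip_um``, ``dist_base_cm``,
        ``dist_tip_cm``, optionally ``total_length_cm``, ``branched``) to the
        file's column names.  Omitted for files with canonical headers.
    units
        Unit hints, e.g. ``{"length": "m", "diameter": "um"}``.  Defaults to
        canonical cm/um.
    daughter_columns
        Columns (file names) holding per-daughter-twig tip counts for
        branched stems; when given, ``n_tip`` is their row-wise sum and the
        record is flagged ``branched``.
    tip_offset_cm
        Apex distance assigned to the tip section when the table carries
        only total branch length.

    Rows that cannot be coerced, or that violate hard invariants (e.g.
    ``dist_tip >= dist_base``), are skipped and listed with their row number
    in ``dataset.load_report``; a missing mandatory column raises.
    """
    df = pd.read_csv(path)
    column_map = dict(column_map or {})
    units = dict(units or {})
    daughter_columns = list(daughter_columns or [])

    # Resolve canonical -> file columns; identity for canonical headers.
    resolved = {}
    for canon in (*CANONICAL_COLUMNS, "total_length_cm"):
        src = column_map.get(canon, canon)
        if src in df.columns:
            resolved[canon] = src

    mandatory = ["species_id", "n_base", "d_base_um", "d_tip_um"]
    if not daughter_columns:
        mandatory.append("n_tip")
    if "dist_base_cm" not in resolved and "total_length_cm" not in resolved:
        mandatory.append("dist_base_cm")
    elif "dist_base_cm" in resolved:
        mandatory.append("dist_tip_cm")
    missing = [c for c in mandatory if c not in resolved]
    if missing:
        raise ValueError(
            f"missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    for c in daughter_columns:
        if c not in df.columns:
            raise ValueError(f"missing daughter column: {c}")

    report = ValidationReport()
    records = []
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):  # 1 = header
        raw = {canon: row[src] for canon, src in resolved.items()}
        for c in daughter_columns:
            raw[c] = row[c]
        rec = _coerce_row(
            rownum, raw, units, daughter_columns, tip_offset_cm, report
        )
        if rec is not None:
            records.append(rec)
    return Dataset(
        records=records,
        provenance=provenance if provenance is not None else str(path),
        load_report=report,
    )


def write_table(dataset: Dataset, path) -> None:
    """Write the dataset as a canonical-header CSV at full float precision."""
    df = dataset.to_frame()[list(CANONICAL_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# Phylogeny
# --------------------------------------------------------------------------


class Phylogeny:
    """A rooted ultrametric tree with branch lengths (chronogram).

    Thin wrapper over a :class:`dendropy.Tree` exposing exactly what the
    phylogenetic regression needs: unique tip labels, the root-to-tip depth,
    the shared-path (Brownian motion) covariance matrix, and pruning.
    """

    #: relative tolerance on tip-depth spread for the ultrametricity check
    ULTRAMETRIC_RTOL = 1e-6

    def __init__(self, tree: dendropy.Tree, check: bool = True):
        self.tree = tree
        self._depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in tree.leaf_node_iter()
        }
        labels = list(self._depths)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        self.tip_labels = sorted(labels)
        depths = np.array([self._depths[t] for t in self.tip_labels])
        self.depth = float(depths.max())
        if check:
            dev = float(np.max(np.abs(depths - self.depth)))
            if dev > self.ULTRAMETRIC_RTOL * self.depth:
                raise ValueError(
                    "tree is not ultrametric: max tip-depth deviation "
                    f"{dev:.6g} exceeds tolerance "
                    f"{self.ULTRAMETRIC_RTOL * self.depth:.6g}"
                )

    def __len__(self) -> int:
        return len(self.tip_labels)

    def vcv(self, labels: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Brownian-motion covariance: entry (i, j) is the root-to-MRCA path.

        Returns the tip label order and the symmetric positive-definite
        matrix; the diagonal holds each tip's root distance (= tree depth on
        an ultrametric tree).
        """
        labels = list(labels) if labels is not None else self.tip_labels
        missing = [l for l in labels if l not in self._depths]
        if missing:
            raise KeyError(f"labels not in tree: {missing}")
        idx = {lbl: i for i, lbl in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        # One postorder pass: each internal node contributes its root
        # distance as the covariance of every cross-child tip pair.
        node_depth = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            node_depth[node] = (node_depth[parent] if parent else 0.0) + edge
        leafsets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lbl = node.taxon.label
                leafsets[node] = (
                    [idx[lbl]] if lbl in idx else []
                )
                if lbl in idx:
                    C[idx[lbl], idx[lbl]] = self._depths[lbl]
                continue
            children = [leafsets.pop(c) for c in node.child_nodes()]
            d = node_depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    if children[a] and children[b]:
                        ia = np.asarray(children[a])
                        ib = np.asarray(children[b])
                        C[np.ix_(ia, ib)] = d
                        C[np.ix_(ib, ia)] = d
            leafsets[node] = [i for ch in children for i in ch]
        return labels, C

    def prune_to(self, labels: list[str]) -> "Phylogeny":
        """New Phylogeny restricted to ``labels`` (order-insensitive)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(keep)
        return Phylogeny(sub)

    def shared_path_matrix(self) -> tuple[list[str], np.ndarray]:
        """Alias for :meth:`vcv` over all tips (tip-to-tip MRCA depths)."""
        return self.vcv()

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick_string(cls, s: str, check: bool = True) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=s, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # normalize parser errors
            raise ValueError(f"cannot parse Newick: {exc}") from exc
        return cls(tree, check=check)


def read_newick(path, check: bool = True) -> Phylogeny:
    """Parse a Newick file into a :class:`Phylogeny`.

    Ultrametricity is verified to the class tolerance; a violation raises a
    ``ValueError`` reporting the maximum tip-depth deviation.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty Newick file: {path}")
    return Phylogeny.from_newick_string(text, check=check)
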