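"""Domain types and I/O for presence-absence matrices, annotations and networks.

The single substrate of every analysis stage is a binary fragment x sample
matrix: rows are T-RFLP terminal restriction fragments (the operational
taxonomic units), columns are samples, and a cell is 1 when the fragment was
detected in the sample. Fragments carry a domain label (bacterial or archaeal)
and samples carry location metadata (core along the groundwater flow path,
depth section, bulk vs single-particle scale).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

BACTERIAL = "bacterial"
ARCHAEAL = "archaeal"
DOMAINS = (BACTERIAL, ARCHAEAL)

CORES = ("C1", "C2", "C3", "C5", "C8")
SCALES = ("bulk", "particle")


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of joint presence counts for a fragment pair.

    ``a`` counts samples with both fragments present, ``b`` only the first,
    ``c`` only the second, ``d`` neither; ``a+b+c+d`` is the sample count.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """Table for the pair with the two fragments exchanged (b <-> c)."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


class PresenceAbsenceMatrix:
    """Binary fragments x samples detection matrix.

    Rows are fragments, columns are samples. Any strictly positive input value
    is coerced to presence (1), so abundance tables are accepted; identifiers
    are opaque strings and must be unique along each axis.
    """

    def __init__(
        self,
        values: np.ndarray,
        fragment_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValidationError("matrix values must be 2-dimensional")
        if values.shape != (len(fragment_ids), len(sample_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match {len(fragment_ids)} fragments "
                f"x {len(sample_ids)} samples"
            )
        if not np.isfinite(values.astype(float)).all():
            raise ValidationError("matrix contains non-finite values")
        if (values.astype(float) < 0).any():
            bad = np.argwhere(values.astype(float) < 0)[0]
            raise ValidationError(
                f"negative cell at fragment {fragment_ids[bad[0]]!r}, sample {sample_ids[bad[1]]!r}"
            )
        self._check_unique(fragment_ids, "fragment")
        self._check_unique(sample_ids, "sample")
        self.values = (values.astype(float) > 0).astype(np.int8)
        self.fragment_ids = list(map(str, fragment_ids))
        self.sample_ids = list(map(str, sample_ids))
        self._frag_index = {f: i for i, f in enumerate(self.fragment_ids)}

    @staticmethod
    def _check_unique(ids: Sequence[str], what: str) -> None:
        counts: dict[str, int] = {}
        for x in map(str, ids):
            counts[x] = counts.get(x, 0) + 1
        dups = [k for k, v in counts.items() if v > 1]
        if dups:
            raise ValidationError(f"duplicate {what} ids: {sorted(dups)}")

    @property
    def n_fragments(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def occupancy(self) -> np.ndarray:
        """Per-fragment number of samples in which it is present (row sums)."""
        return self.values.sum(axis=1, dtype=np.int64)

    @property
    def richness(self) -> np.ndarray:
        """Per-sample number of fragments present (column sums)."""
        return self.values.sum(axis=0, dtype=np.int64)

    def fragment_index(self, fragment_id: str) -> int:
        try:
            return self._frag_index[fragment_id]
        except KeyError:
            raise KeyError(f"unknown fragment id {fragment_id!r}") from None

    def row(self, fragment_id: str) -> np.ndarray:
        return self.values[self.fragment_index(fragment_id)]

    def samples_of(self, fragment_id: str) -> set[str]:
        row = self.row(fragment_id)
        return {s for s, v in zip(self.sample_ids, row) if v}

    def contingency_table(self, i: str, j: str) -> ContingencyTable2x2:
        """Joint presence table for fragments ``i`` (first) and ``j`` (second)."""
        if i == j:
            raise ValidationError("contingency table requires two distinct fragments")
        ri, rj = self.row(i), self.row(j)
        a = int(np.sum(ri & rj))
        b = int(np.sum(ri) - a)
        c = int(np.sum(rj) - a)
        d = int(self.n_samples - a - b - c)
        return ContingencyTable2x2(a, b, c, d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.fragment_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceAbsenceMatrix":
        return cls(frame.to_numpy(), list(map(str, frame.index)), list(map(str, frame.columns)))

    @classmethod
    def read(cls, path: str | Path, dialect: str | None = None) -> "PresenceAbsenceMatrix":
        """Read a matrix from TSV/CSV: header row of sample ids, first column fragment ids."""
        sep = _separator(path, dialect)
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except ValueError as exc:
            raise ValidationError(f"failed to parse matrix file {path}: {exc}") from exc
        for col in frame.columns:
            non_numeric = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if non_numeric.any():
                row_id = frame.index[non_numeric.to_numpy().argmax()]
                raise ValidationError(
                    f"non-numeric cell at fragment {row_id!r}, sample {col!r} in {path}"
                )
        return cls.from_frame(frame.apply(pd.to_numeric))

    def write(self, path: str | Path, dialect: str | None = None) -> None:
        sep = _separator(path, dialect)
        self.to_frame().to_csv(path, sep=sep, index_label="fragment_id")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.fragment_ids == other.fragment_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


def _separator(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValidationError(f"unknown dialect {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if str(path).endswith(".csv") else "\t"


@dataclass(frozen=True)
class FragmentAnnotation:
    """Domain label and optional taxonomy for one fragment.

    ``species_candidates`` may hold several names when the T-RFLP fragment
    length did not map to a single species; files store them slash-separated.
    """

    fragment_id: str
    domain: str
    enzyme: str | None = None
    species_candidates: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(
                f"domain of {self.fragment_id!r} must be one of {DOMAINS}, got {self.domain!r}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    """Location metadata for one sample."""

    sample_id: str
    core: str
    depth_section: int
    scale: str
    particle_index: int | None = None

    def __post_init__(self) -> None:
        if self.core not in CORES:
            raise ValidationError(f"core must be one of {CORES}, got {self.core!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if (self.particle_index is not None) != (self.scale == "particle"):
            raise ValidationError(
                f"sample {self.sample_id!r}: particle_index must be present iff scale='particle'"
            )


def read_annotations(path: str | Path) -> dict[str, FragmentAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, FragmentAnnotation] = {}
    for rec in frame.to_dict("records"):
        fid = str(rec["fragment_id"])
        if fid in out:
            raise ValidationError(f"duplicate fragment id in annotation: {fid!r}")
        species = tuple(s for s in str(rec.get("species", "")).split("/") if s)
        out[fid] = FragmentAnnotation(
            fragment_id=fid,
            domain=str(rec["domain"]),
            enzyme=str(rec["enzyme"]) or None if "enzyme" in rec else None,
            species_candidates=species,
        )
    return out


def write_annotations(annotations: Mapping[str, FragmentAnnotation], path: str | Path) -> None:
    rows = [
        {
            "fragment_id": a.fragment_id,
            "domain": a.domain,
            "enzyme": a.enzyme or "",
            "species": "/".join(a.species_candidates),
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows, columns=["fragment_id", "domain", "enzyme", "species"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, SampleMetadata] = {}
    for rec in frame.to_dict("records"):
        sid = str(rec["sample_id"])
        if sid in out:
            raise ValidationError(f"duplicate sample id in metadata: {sid!r}")
        pi = str(rec.get("particle_index", ""))
        out[sid] = SampleMetadata(
            sample_id=sid,
            core=str(rec["core"]),
            depth_section=int(rec["depth_section"]),
            scale=str(rec["scale"]),
            particle_index=int(pi) if pi else None,
        )
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "core": m.core,
            "depth_section": m.depth_section,
            "scale": m.scale,
            "particle_index": "" if m.particle_index is None else m.particle_index,
        }
        for m in metadata.values()
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "core", "depth_section", "scale", "particle_index"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network exports


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """Write a (di)graph to GraphML; node/edge attributes are preserved."""
    nx.write_graphml(net, str(path), named_key_ids=True)


def read_graphml(path: str | Path, directed: bool | None = None) -> nx.Graph:
    g = nx.read_graphml(str(path))
    if directed is True and not g.is_directed():
        g = g.to_directed()
    if directed is False and g.is_directed():
        g = g.to_undirected()
    return g


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Plain TSV edge list.

    Undirected signed networks get columns (node1, node2, sign, p_adj);
    directed rule networks get (origin, target, support_origin).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        if net.is_directed():
            writer.writerow(["origin", "target", "support_origin"])
            for u, v, attrs in net.edges(data=True):
                writer.writerow([u, v, attrs.get("support_origin", "")])
        else:
            writer.writerow(["node1", "node2", "sign", "p_adj"])
            for u, v, attrs in net.edges(data=True):
                writer.writerow([u, v, attrs.get("sign", ""), attrs.get("p_adj", "")])


def write_rules(rules: Iterable, path: str | Path, annotations: Mapping[str, FragmentAnnotation] | None = None, correlated_pairs: set[frozenset] | None = None) -> None:
    """Rules TSV: origin, target, support_origin, origin_domain, target_domain, also_correlated."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["origin", "target", "support_origin", "origin_domain", "target_domain", "also_correlated"]
        )
        for r in rules:
            od = annotations[r.origin].domain if annotations else ""
            td = annotations[r.target].domain if annotations else ""
            corr = (
                frozenset((r.origin, r.target)) in correlated_pairs
                if correlated_pairs is not None
                else ""
            )
            writer.writerow([r.origin, r.target, r.support_origin, od, td, corr])
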