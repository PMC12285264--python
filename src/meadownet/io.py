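"""Core data types and file I/O for compartment-resolved amplicon tables.

The central container is :class:`FeatureTable`, a samples x taxa abundance
matrix in either ``count`` or ``relative`` mode, accompanied by a
:class:`TaxonomyTable` (ranked lineages with the usual d/k/p/c/o/f/g/s
prefixes) and :class:`SampleMetadata` (compartment code, sampling month and
the measured physicochemical variables).

On disk, OTU tables follow the common QIIME-style export convention of taxa
as rows and samples as columns; the reader normalizes everything to the
internal samples x taxa orientation. A BIOM-style JSON file (rows =
observations, columns = samples) is accepted by the same reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("d", "k", "p", "c", "o", "f", "g", "s")

COMPARTMENTS = ("s", "bk", "rp", "rt", "rz", "w", "lp", "lf")
"""Valid compartment codes: non-seagrass sediment (s), bulk sediment (bk),
rhizosphere sediment (rp), root (rt), rhizome (rz), water (w), leaf
phylloplane (lp) and leaf tissue (lf)."""

_UNCLASSIFIED_SENTINELS = {"", "unidentified", "unclassified", "na", "nan", "none"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class FeatureTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id with taxon ids as columns. Values must
        be non-negative; integral in ``count`` mode; per-sample row sums of 1
        in ``relative`` mode.
    mode :
        ``"count"`` or ``"relative"``.
    """

    data: pd.DataFrame
    mode: str = "count"

    def __post_init__(self) -> None:
        if self.mode not in ("count", "relative"):
            raise ValueError(f"mode must be 'count' or 'relative', got {self.mode!r}")
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "taxon")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.min(values) < 0:
            raise ValueError("abundance values must be non-negative")
        if self.mode == "count":
            if values.size and not np.allclose(values, np.round(values)):
                raise ValueError("count-mode table contains non-integer values")
            self.data = self.data.round().astype(np.int64)
        else:
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValueError(
                    f"relative-mode rows must sum to 1; offending sample "
                    f"{self.data.index[bad[0]]!r} sums to {sums[bad[0]]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return FeatureTable(self.data.loc[ids].copy(), mode=self.mode)

    def subset_taxa(self, taxon_ids: Iterable[str]) -> "FeatureTable":
        ids = list(taxon_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown taxon ids: {sorted(missing)}")
        # relative-mode rows no longer sum to 1 after dropping taxa
        if self.mode == "relative":
            raise ValueError("subset_taxa is only defined for count-mode tables")
        return FeatureTable(self.data[ids].copy(), mode=self.mode)

    def concat_taxa(self, other: "FeatureTable") -> "FeatureTable":
        """Join two count tables over the same samples (e.g. fungi + prokaryotes)."""
        if self.mode != "count" or other.mode != "count":
            raise ValueError("concat_taxa requires count-mode tables")
        if list(self.data.index) != list(other.data.index):
            raise ValueError("tables must share an identical sample ordering")
        return FeatureTable(pd.concat([self.data, other.data], axis=1), mode="count")


def parse_lineage(lineage: str) -> list[tuple[str, str]]:
    """Parse ``"k__Fungi;p__Ascomycota;..."`` into ordered (rank, name) pairs.

    Unknown or unclassified sentinels (``g__unidentified`` etc.) are dropped.
    """
    pairs: list[tuple[str, str]] = []
    for part in str(lineage).split(";"):
        part = part.strip()
        if not part:
            continue
        if "__" in part:
            rank, name = part.split("__", 1)
        else:
            continue
        rank = rank.strip().lower()
        name = name.strip()
        if rank not in RANKS:
            continue
        if name.lower() in _UNCLASSIFIED_SENTINELS:
            continue
        pairs.append((rank, name))
    return pairs


@dataclass
class TaxonomyTable:
    """Mapping of taxon id to a ranked lineage string."""

    lineages: dict[str, str]

    def __post_init__(self) -> None:
        self._parsed = {t: parse_lineage(s) for t, s in self.lineages.items()}

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def lineage(self, taxon_id: str) -> list[tuple[str, str]]:
        return self._parsed[taxon_id]

    def name_at_rank(self, taxon_id: str, rank: str) -> str | None:
        for r, name in self._parsed[taxon_id]:
            if r == rank:
                return name
        return None

    def domain(self, taxon_id: str) -> str:
        """Domain label (fungi / bacteria / archaea), derived from the top ranks."""
        for r, name in self._parsed[taxon_id]:
            low = name.lower()
            if r in ("d", "k"):
                if low == "fungi":
                    return "fungi"
                if low == "bacteria":
                    return "bacteria"
                if low == "archaea":
                    return "archaea"
        raise ValueError(f"cannot derive domain for taxon {taxon_id!r}")

    def domains(self, taxon_ids: Iterable[str]) -> dict[str, str]:
        return {t: self.domain(t) for t in taxon_ids}


@dataclass
class SampleMetadata:
    """Per-sample compartment, month and physicochemical measurements.

    ``data`` is indexed by sample id with columns
    (compartment, month, pH, temperature, salinity).
    """

    data: pd.DataFrame

    REQUIRED = ("compartment", "month", "pH", "temperature", "salinity")

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad = set(self.data["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment codes: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def compartment(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "compartment"])

    def samples_in(self, compartments: Iterable[str]) -> list[str]:
        comps = set(compartments)
        bad = comps - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment codes: {sorted(bad)}")
        mask = self.data["compartment"].isin(comps)
        return list(self.data.index[mask])

    def validate_against(self, table: FeatureTable) -> None:
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc.get("shape", (len(taxa), len(samples))))
    mat = np.zeros(shape, dtype=float)
    if doc.get("matrix_type", "dense") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    # BIOM rows are observations (taxa): transpose to samples x taxa
    return pd.DataFrame(mat.T, index=samples, columns=taxa)


def _read_tsv_matrix(path: Path, orientation: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "header")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(list(df.index), "row")
    if orientation == "taxa_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index.name = None
    df.columns.name = None
    return df


def read_feature_table(
    path: str | Path, mode: str = "count", orientation: str = "taxa_rows"
) -> FeatureTable:
    """Read an OTU table from TSV (taxa rows x sample columns by default) or
    BIOM-style JSON (``.biom`` / ``.json`` extension)."""
    path = Path(path)
    if path.suffix.lower() in (".biom", ".json"):
        df = _read_biom_json(path)
    else:
        df = _read_tsv_matrix(path, orientation)
    return FeatureTable(df, mode=mode)


def write_feature_table(
    table: FeatureTable, path: str | Path, orientation: str = "taxa_rows"
) -> None:
    df = table.data.T if orientation == "taxa_rows" else table.data
    label = "taxon_id" if orientation == "taxa_rows" else "sample_id"
    df.to_csv(path, sep="\t", index_label=label)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy table needs two columns: taxon_id, lineage")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(list(ids), "taxon")
    return TaxonomyTable(dict(zip(ids, df.iloc[:, 1].astype(str))))


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    pd.DataFrame(
        {"taxon_id": list(taxonomy.lineages), "lineage": list(taxonomy.lineages.values())}
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def to_relative(table: FeatureTable) -> FeatureTable:
    """Convert per-sample counts to relative fractions (rows sum to 1)."""
    if table.mode == "relative":
        return table
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample cannot be normalized: {zero.index[0]!r}")
    return FeatureTable(table.data.div(totals, axis=0), mode="relative")


def aggregate_by_rank(
    table: FeatureTable, taxonomy: TaxonomyTable, rank: str
) -> FeatureTable:
    """Collapse taxa at a taxonomic rank, conserving per-sample totals.

    Taxa unclassified at ``rank`` fall into one bucket per deepest classified
    ancestor, labelled ``"<rank>__<name> (unclassified)"`` (or plain
    ``"unclassified"`` when the lineage is empty), so the aggregation loses no
    abundance.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank symbol {rank!r}; expected one of {RANKS}")
    labels = []
    for taxon in table.taxon_ids:
        if taxon not in taxonomy:
            raise KeyError(f"taxon {taxon!r} missing from taxonomy")
        name = taxonomy.name_at_rank(taxon, rank)
        if name is not None:
            labels.append(f"{rank}__{name}")
        else:
            lineage = taxonomy.lineage(taxon)
            if lineage:
                deep_rank, deep_name = lineage[-1]
                labels.append(f"{deep_rank}__{deep_name} (unclassified)")
            else:
                labels.append("unclassified")
    grouped = table.data.T.groupby(pd.Index(labels, name="taxon")).sum().T
    return FeatureTable(grouped, mode=table.mode)


def taxon_share_within_group(
    table: FeatureTable, member_taxa: Iterable[str], group_taxa: Iterable[str]
) -> pd.Series:
    """Fraction of a taxon group's total (all-sample) abundance held by each member.

    E.g. the proportion of the genus-level *Vibrio* community contributed by
    each *Vibrio* OTU. Fractions over the whole group sum to 1.
    """
    members = list(member_taxa)
    group = list(group_taxa)
    if not set(members) <= set(group):
        raise ValueError("member_taxa must be a subset of group_taxa")
    totals = table.data[group].sum(axis=0)
    group_total = float(totals.sum())
    if group_total <= 0:
        raise ValueError("taxon group has zero total abundance")
    return totals[members] / group_total
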