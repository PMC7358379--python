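"""Experimental-design and file I/O layer.

Multiplexed isobaric (TMT) experiments are organised in *plexes*: batches
of up to 11 channels analysed in one MS run.  Each channel carries either a
treatment/control replicate or a *pooled reference* — an equal mixture of
every sample in the study that serves as the per-plex denominator and the
bridge between plexes.  This module holds the design and annotation
containers, the tab-separated readers/writers for them, and the structural
validation the downstream quantification relies on.

All files are UTF-8, tab-separated, with a header row.  Empty strings and
``NA`` both denote missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical group name marking a pooled-reference channel (matched
#: case-insensitively on input)
POOLED_REF = "POOLED_REF"

MITOCHONDRIAL = "mitochondrial"
NON_MITOCHONDRIAL = "non-mitochondrial"

#: annotation columns captured from intensity tables when present
ANNOTATION_COLUMNS = ("gene_symbol", "localization", "psm_count")

_NA_VALUES = ("", "NA")


class ValidationError(ValueError):
    """An input file or design violates a structural invariant."""


@dataclass(frozen=True)
class Channel:
    """One TMT channel: a tag label carrying one labelled sample."""

    channel: str
    sample_id: str
    group: str
    replicate: int

    @property
    def is_reference(self) -> bool:
        return self.group == POOLED_REF


@dataclass
class PlexDesign:
    """Channel layout of a single TMT plex.

    Invariants (enforced by :meth:`validate`): channel labels are unique
    within the plex, at least one channel is a pooled reference, and
    replicate indices are positive.
    """

    plex_id: str
    channels: list[Channel]

    def validate(self) -> None:
        seen: set[str] = set()
        for ch in self.channels:
            if ch.channel in seen:
                raise ValidationError(
                    f"plex {self.plex_id!r}: duplicate channel {ch.channel!r}"
                )
            seen.add(ch.channel)
            if ch.replicate < 1:
                raise ValidationError(
                    f"plex {self.plex_id!r}, channel {ch.channel!r}: "
                    f"replicate must be a positive integer, got {ch.replicate}"
                )
        if not any(ch.is_reference for ch in self.channels):
            raise ValidationError(
                f"plex {self.plex_id!r} has no {POOLED_REF} channel"
            )

    @property
    def reference_channels(self) -> list[str]:
        return [ch.channel for ch in self.channels if ch.is_reference]

    @property
    def sample_channels(self) -> list[Channel]:
        return [ch for ch in self.channels if not ch.is_reference]

    @property
    def channel_labels(self) -> list[str]:
        return [ch.channel for ch in self.channels]

    def groups(self) -> list[str]:
        out: list[str] = []
        for ch in self.sample_channels:
            if ch.group not in out:
                out.append(ch.group)
        return out


def validate_designs(designs: Sequence[PlexDesign]) -> None:
    """Cross-plex validation of a full study design.

    Checks each plex individually, then that non-reference sample ids are
    unique across the whole study (a sample is labelled exactly once) and
    that every group has at least two replicates so a t-test has variance
    to work with.
    """
    if not designs:
        raise ValidationError("no plexes in design")
    ids = [d.plex_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate plex_id in design: {ids}")
    for d in designs:
        d.validate()
    seen: dict[str, str] = {}
    group_reps: dict[str, int] = {}
    for d in designs:
        for ch in d.sample_channels:
            if ch.sample_id in seen:
                raise ValidationError(
                    f"sample {ch.sample_id!r} appears in plex "
                    f"{seen[ch.sample_id]!r} and plex {d.plex_id!r}"
                )
            seen[ch.sample_id] = d.plex_id
            group_reps[ch.group] = group_reps.get(ch.group, 0) + 1
    for group, n in group_reps.items():
        if n < 2:
            raise ValidationError(
                f"group {group!r} has only {n} replicate; at least 2 required"
            )


@dataclass
class ReporterIntensityTable:
    """Protein-level summed reporter-ion intensities for one plex.

    ``data`` is indexed by protein accession with one float column per
    channel of the referenced design (NaN = missing); ``annotations`` holds
    any of gene_symbol / localization / psm_count found in the input.
    """

    plex_id: str
    data: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    def validate(self, design: PlexDesign) -> None:
        if self.plex_id != design.plex_id:
            raise ValidationError(
                f"table plex {self.plex_id!r} != design plex {design.plex_id!r}"
            )
        if list(self.data.columns) != design.channel_labels:
            raise ValidationError(
                f"plex {self.plex_id!r}: table columns {list(self.data.columns)} "
                f"do not match design channels {design.channel_labels}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"plex {self.plex_id!r}: duplicate accession(s) {dups}"
            )
        if (self.data < 0).any().any():
            raise ValidationError(f"plex {self.plex_id!r}: negative intensity")


@dataclass
class PathwayAnnotation:
    """A named gene set: the full annotated universe of one pathway."""

    pathway_id: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id!r} has no members")


# ---------------------------------------------------------------------------
# readers / writers


def read_design(path: str | Path) -> list[PlexDesign]:
    """Read plex designs from a TSV with columns
    plex_id, channel, sample_id, group, replicate.

    ``POOLED_REF`` group labels are recognised case-insensitively.  The
    returned designs are validated individually and as a study.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["plex_id", "channel", "sample_id", "group", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing design column(s) {missing}")
    designs: list[PlexDesign] = []
    by_plex: dict[str, list[Channel]] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        group = row["group"].strip()
        if group.upper() == POOLED_REF:
            group = POOLED_REF
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise ValidationError(
                f"{path}, line {i + 2}: replicate {row['replicate']!r} "
                "is not an integer"
            ) from exc
        pid = row["plex_id"].strip()
        if pid not in by_plex:
            by_plex[pid] = []
            order.append(pid)
        by_plex[pid].append(
            Channel(row["channel"].strip(), row["sample_id"].strip(), group, rep)
        )
    designs = [PlexDesign(pid, by_plex[pid]) for pid in order]
    validate_designs(designs)
    return designs


def write_design(designs: Sequence[PlexDesign], path: str | Path) -> None:
    rows = [
        (d.plex_id, ch.channel, ch.sample_id, ch.group, ch.replicate)
        for d in designs
        for ch in d.channels
    ]
    pd.DataFrame(
        rows, columns=["plex_id", "channel", "sample_id", "group", "replicate"]
    ).to_csv(path, sep="\t", index=False)


def read_intensity_table(
    path: str | Path, design: PlexDesign
) -> ReporterIntensityTable:
    """Read a protein-level reporter-intensity export for one plex.

    The header must contain an ``accession`` column and one intensity
    column per design channel; blank or ``NA`` cells mean missing.
    Annotation columns (gene_symbol, localization, psm_count) are captured
    when present.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=None
    )
    cols_lower = {c.lower(): c for c in df.columns}
    if "accession" not in cols_lower:
        raise ValidationError(f"{path}: no accession column")
    acc_col = cols_lower["accession"]
    for ch in design.channel_labels:
        if ch not in df.columns:
            raise ValidationError(
                f"{path}: missing intensity column for channel {ch!r}"
            )
    acc = df[acc_col].str.strip()
    if acc.duplicated().any():
        dups = acc[acc.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate accession(s) {dups}")

    data = df[design.channel_labels].replace(list(_NA_VALUES), np.nan)
    try:
        data = data.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric intensity: {exc}") from exc
    data.index = pd.Index(acc, name="accession")
    neg = data.lt(0)
    if neg.any().any():
        r = neg.any(axis=1).idxmax()
        c = neg.loc[r].idxmax()
        raise ValidationError(
            f"{path}: negative intensity for protein {r!r}, channel {c!r}"
        )

    ann_cols = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    annotations = df[ann_cols].copy() if ann_cols else pd.DataFrame(index=acc)
    annotations.index = data.index
    if "psm_count" in annotations.columns:
        annotations["psm_count"] = pd.to_numeric(
            annotations["psm_count"].replace(list(_NA_VALUES), pd.NA)
        )
    table = ReporterIntensityTable(design.plex_id, data, annotations)
    table.validate(design)
    return table


def write_intensity_table(
    table: ReporterIntensityTable, path: str | Path
) -> None:
    out = table.annotations.join(table.data, how="right")
    out.insert(0, "accession", out.index)
    # integer-valued intensities are written without a decimal point so a
    # round-trip is bit-exact
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read gene sets from a GMT file (name TAB description TAB members...)."""
    pathways: list[PathwayAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}, line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, source, *members = fields
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                raise ValidationError(
                    f"{path}, line {lineno}: duplicate members in {name!r}"
                )
            try:
                pathways.append(PathwayAnnotation(name, frozenset(members), source))
            except ValidationError as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return pathways


def write_gmt(pathways: Iterable[PathwayAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pathways:
            members = "\t".join(sorted(p.members))
            fh.write(f"{p.pathway_id}\t{p.source}\t{members}\n")


def _read_two_column(
    path: str | Path, key: str, value: str
) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header:
            cols = header.split("\t")
            if len(cols) != 2:
                raise ValidationError(
                    f"{path}: expected 2 columns ({key}, {value}), got {cols}"
                )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0]:
                raise ValidationError(
                    f"{path}, line {lineno}: malformed line {line!r}"
                )
            k, v = fields
            if k in mapping and mapping[k] != v:
                raise ValidationError(
                    f"{path}, line {lineno}: conflicting duplicate entry for {k!r}"
                )
            mapping[k] = v
    return mapping


def read_localization(path: str | Path) -> dict[str, str]:
    """Read an accession → subcellular-localization map (two-column TSV).

    Tags are normalised to a binary partition: anything equal to
    ``mitochondrial`` (case-insensitive) is mitochondrial, everything else
    is non-mitochondrial.  Accessions absent from the map default to
    non-mitochondrial downstream, with a logged count.
    """
    raw = _read_two_column(path, "accession", "localization")
    return {
        k: (MITOCHONDRIAL if v.strip().lower() == MITOCHONDRIAL else NON_MITOCHONDRIAL)
        for k, v in raw.items()
    }


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read an accession → functional-class map (two-column TSV)."""
    return _read_two_column(path, "accession", "functional_class")


def write_two_column(
    mapping: Mapping[str, str], path: str | Path, key: str, value: str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{key}\t{value}\n")
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")


def apply_localization(
    proteins: Iterable[str], mapping: Mapping[str, str]
) -> pd.Series:
    """Tag each protein mitochondrial / non-mitochondrial.

    Unknown accessions default to non-mitochondrial; the count of defaults
    is logged so silently missing annotation is visible.
    """
    proteins = list(proteins)
    tags = []
    n_unknown = 0
    for p in proteins:
        tag = mapping.get(p)
        if tag is None:
            n_unknown += 1
            tag = NON_MITOCHONDRIAL
        tags.append(tag)
    if n_unknown:
        logger.info(
            "%d/%d proteins had no localization annotation; "
            "defaulted to non-mitochondrial",
            n_unknown,
            len(proteins),
        )
    return pd.Series(tags, index=pd.Index(proteins, name="accession"), name="localization")
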