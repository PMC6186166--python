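"""Shared domain types and plain-text readers/writers.

The pipeline moves four kinds of objects between stages:

* :class:`CountMatrix` — a gene x sample matrix of non-negative integer
  read counts with a two-level sample grouping (the disease contrast)
  and optional gene lengths.
* :class:`GeneSignature` — the up/down differentially-expressed gene
  lists that summarise a contrast, with provenance (subsampling
  fraction, iteration, filter thresholds).
* :class:`ReferenceLibrary` — perturbagen x cell-line profiles of
  per-gene differential-expression scores over a common gene universe,
  with free-form cell-line tags (e.g. ``"neuronal"``).
* :class:`ConnectionResult` — one scored, significance-assessed
  compound–signature association, classified as reversing (``rev``) or
  progressing (``prog``).

All file formats are plain text: TSV count matrices, GMT/GRP signature
files, long-format TSV or GCT 1.3 libraries.  Parsers never silently
coerce — malformed tokens raise a located error — and every
write-then-read cycle is a fixed point on the parsed representation.
Gene identifiers are case-sensitive opaque strings matched exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sigdepth")

__all__ = [
    "SigdepthError",
    "FormatError",
    "ConsistencyError",
    "ContrastError",
    "IntegrityError",
    "ConfigError",
    "DomainError",
    "CoverageError",
    "NormalizationError",
    "DegenerateInputError",
    "CountMatrix",
    "GeneSignature",
    "ReferenceLibrary",
    "ConnectionResult",
    "read_counts",
    "write_counts",
    "read_signature_gmt",
    "write_signature_gmt",
    "read_signature_grp",
    "write_signature_grp",
    "read_reference_library",
    "write_library_long",
    "write_library_gct",
    "connections_to_frame",
    "write_connections",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# Errors

class SigdepthError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SigdepthError):
    """A file violates its declared format (located where possible)."""


class ConsistencyError(SigdepthError):
    """Two inputs that must agree (e.g. counts vs groups) do not."""


class ContrastError(SigdepthError):
    """The sample grouping does not define a two-level contrast."""


class IntegrityError(SigdepthError):
    """A parsed object violates a structural invariant (e.g. up/down overlap)."""


class ConfigError(SigdepthError):
    """Invalid configuration value."""


class DomainError(SigdepthError):
    """Argument outside its mathematical domain."""


class CoverageError(SigdepthError):
    """A signature has no genes in common with the library universe."""


class NormalizationError(SigdepthError):
    """Size-factor estimation is impossible on this matrix."""


class DegenerateInputError(SigdepthError):
    """Input is degenerate for the requested fit (e.g. all flags equal)."""


# ---------------------------------------------------------------------------
# CountMatrix

@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    ``groups`` assigns every sample to one of exactly two levels; the
    differential-expression contrast is second-level vs first-level in
    lexicographic order (``log2 FC = B vs A``).  ``gene_lengths``, when
    present, covers every gene (bases, positive).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    groups: list[str]
    gene_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                g, s = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count {self.counts[g, s]} at gene "
                    f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ConsistencyError("one group label required per sample")
        levels = sorted(set(self.groups))
        if len(levels) != 2:
            raise ContrastError(
                f"expected exactly two group levels, got {levels}"
            )
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.int64)
            if self.gene_lengths.shape != (len(self.gene_ids),):
                raise ConsistencyError("gene_lengths must cover every gene")
            if np.any(self.gene_lengths <= 0):
                raise FormatError("gene lengths must be positive")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def group_levels(self) -> tuple[str, str]:
        """Contrast levels (A, B), sorted; log2 FC reported as B vs A."""
        lv = sorted(set(self.groups))
        return lv[0], lv[1]

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.group_levels
        g = np.asarray(self.groups)
        return g == a, g == b

    def depths(self) -> np.ndarray:
        """Per-sample library size (column sums)."""
        return self.counts.sum(axis=0)

    def copy(self) -> "CountMatrix":
        return replace(
            self,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts.copy(),
            groups=list(self.groups),
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths.copy(),
        )

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        idx = [self.gene_ids.index(g) for g in keep]
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :].copy(),
            groups=list(self.groups),
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths[idx].copy(),
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_counts(path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene id, header sample ids)
    plus a two-column ``sample<TAB>group`` file.

    Sample order follows the counts header.  Non-integer, negative or
    non-numeric entries raise :class:`FormatError` naming the offending
    gene and sample; a sample missing from the groups file raises
    :class:`ConsistencyError`; more than two group levels raise
    :class:`ContrastError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        g, s = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric count {df.iat[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    arr = values.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        g, s = np.argwhere(np.mod(arr, 1) != 0)[0]
        raise FormatError(
            f"{path}: non-integer count {arr[g, s]} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if np.any(arr < 0):
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )

    group_map = _read_group_map(groups_path)
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise ConsistencyError(
            f"{groups_path}: sample {missing[0]!r} present in counts but "
            "missing from groups file"
        )
    groups = [group_map[s] for s in df.columns]
    if len(set(group_map.values())) > 2:
        raise ContrastError(
            f"{groups_path}: more than two group levels: "
            f"{sorted(set(group_map.values()))}"
        )
    return CountMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=arr.astype(np.int64),
        groups=groups,
    )


def _read_group_map(groups_path: str | Path) -> dict[str, str]:
    group_map: dict[str, str] = {}
    with open(groups_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{groups_path}:{lineno}: expected 'sample<TAB>group', "
                    f"got {line!r}"
                )
            if parts[0] == "sample" and parts[1] == "group" and lineno == 1:
                continue  # optional header
            if parts[0] in group_map:
                raise FormatError(
                    f"{groups_path}:{lineno}: duplicate sample {parts[0]!r}"
                )
            group_map[parts[0]] = parts[1]
    return group_map


def write_counts(cm: CountMatrix, path: str | Path, groups_path: str | Path | None = None) -> None:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            for s, g in zip(cm.sample_ids, cm.groups):
                fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# GeneSignature

@dataclass(frozen=True)
class GeneSignature:
    """Up/down gene lists summarising a two-group contrast.

    ``scores`` optionally carries the per-gene signed statistic (log2
    fold change) for member genes.  ``provenance`` records at least the
    subsampling fraction ``f`` (1.0 for the full-data signature), the
    iteration index and the filter thresholds that produced the lists.
    """

    name: str
    up: frozenset[str]
    down: frozenset[str]
    scores: Mapping[str, float] | None = None
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise IntegrityError(
                f"signature {self.name!r}: genes in both up and down: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    @property
    def is_empty(self) -> bool:
        return not (self.up or self.down)


def _provenance_str(prov: Mapping[str, object]) -> str:
    if not prov:
        return "na"
    return " ".join(f"{k}={prov[k]}" for k in sorted(prov))


def _parse_provenance(desc: str) -> dict[str, object]:
    prov: dict[str, object] = {}
    if desc in ("", "na"):
        return prov
    for token in desc.split():
        if "=" not in token:
            continue
        k, v = token.split("=", 1)
        try:
            prov[k] = int(v)
        except ValueError:
            try:
                prov[k] = float(v)
            except ValueError:
                prov[k] = v
    return prov


def write_signature_gmt(sig: GeneSignature, path: str | Path) -> None:
    """Write the two-line GMT dialect: ``<name>_UP`` and ``<name>_DN``
    lines, description field carrying ``key=value`` provenance."""
    desc = _provenance_str(sig.provenance)
    with open(path, "w") as fh:
        fh.write("\t".join([f"{sig.name}_UP", desc, *sorted(sig.up)]) + "\n")
        fh.write("\t".join([f"{sig.name}_DN", desc, *sorted(sig.down)]) + "\n")


def read_signature_gmt(path: str | Path) -> GeneSignature:
    path = Path(path)
    ups: dict[str, tuple[str, list[str]]] = {}
    dns: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
            label, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if label.endswith("_UP"):
                ups[label[:-3]] = (desc, members)
            elif label.endswith("_DN"):
                dns[label[:-3]] = (desc, members)
            else:
                raise FormatError(
                    f"{path}:{lineno}: set name {label!r} must end in _UP or _DN"
                )
    names = set(ups) | set(dns)
    if len(names) != 1:
        raise FormatError(f"{path}: expected one signature, found {sorted(names)}")
    name = names.pop()
    if name not in ups or name not in dns:
        raise FormatError(f"{path}: missing paired _UP/_DN line for {name!r}")
    desc, up = ups[name]
    _, down = dns[name]
    if set(up) & set(down):
        raise IntegrityError(
            f"{path}: signature {name!r} has genes in both _UP and _DN"
        )
    return GeneSignature(name=name, up=frozenset(up), down=frozenset(down),
                         provenance=_parse_provenance(desc))


def write_signature_grp(sig: GeneSignature, stem: str | Path) -> tuple[Path, Path]:
    """Write the paired GRP dialect (one gene per line) to
    ``<stem>_UP.grp`` and ``<stem>_DN.grp``."""
    stem = Path(stem)
    up_path = stem.with_name(stem.name + "_UP.grp")
    dn_path = stem.with_name(stem.name + "_DN.grp")
    up_path.write_text("".join(f"{g}\n" for g in sorted(sig.up)))
    dn_path.write_text("".join(f"{g}\n" for g in sorted(sig.down)))
    return up_path, dn_path


def read_signature_grp(stem: str | Path, name: str | None = None) -> GeneSignature:
    stem = Path(stem)
    up_path = stem.with_name(stem.name + "_UP.grp")
    dn_path = stem.with_name(stem.name + "_DN.grp")
    for p in (up_path, dn_path):
        if not p.exists():
            raise FormatError(f"missing paired GRP file {p}")
    up = {ln.strip() for ln in up_path.read_text().splitlines() if ln.strip()}
    down = {ln.strip() for ln in dn_path.read_text().splitlines() if ln.strip()}
    if up & down:
        raise IntegrityError(f"{stem}: overlapping up/down GRP sets")
    return GeneSignature(name=name or stem.name, up=frozenset(up), down=frozenset(down))


# ---------------------------------------------------------------------------
# ReferenceLibrary

@dataclass
class ReferenceLibrary:
    """Perturbagen x cell-line profiles of per-gene DE scores.

    ``scores`` is a dense |gene_universe| x n_profiles float matrix;
    profile ``i`` is ``(perturbagens[i], cell_lines[i])`` and those
    pairs are unique.  ``cell_line_tags`` maps cell-line ids to tag
    sets used for subsetting (e.g. only ``"neuronal"`` lines).
    """

    gene_universe: list[str]
    scores: np.ndarray
    perturbagens: list[str]
    cell_lines: list[str]
    cell_line_tags: dict[str, set[str]] = field(default_factory=dict)
    n_imputed: int = 0

    def __post_init__(self) -> None:
        self.gene_universe = [str(g) for g in self.gene_universe]
        self.scores = np.asarray(self.scores, dtype=float)
        n_profiles = len(self.perturbagens)
        if len(self.cell_lines) != n_profiles:
            raise ConsistencyError("perturbagens and cell_lines length mismatch")
        if self.scores.shape != (len(self.gene_universe), n_profiles):
            raise ConsistencyError(
                f"scores shape {self.scores.shape} != "
                f"({len(self.gene_universe)}, {n_profiles})"
            )
        if not np.all(np.isfinite(self.scores)):
            raise FormatError("profile scores must be finite")
        pairs = list(zip(self.perturbagens, self.cell_lines))
        if len(set(pairs)) != n_profiles:
            raise FormatError("duplicate (perturbagen, cell_line) profile")
        self._gene_index = {g: i for i, g in enumerate(self.gene_universe)}

    @property
    def n_profiles(self) -> int:
        return len(self.perturbagens)

    @property
    def perturbagen_ids(self) -> list[str]:
        """Unique perturbagen ids in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.perturbagens:
            seen.setdefault(p)
        return list(seen)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Indices of the given genes that exist in the universe."""
        return np.array(
            [self._gene_index[g] for g in genes if g in self._gene_index],
            dtype=np.intp,
        )

    def profile_columns(self, perturbagen: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.perturbagens) if p == perturbagen],
            dtype=np.intp,
        )

    def filter_cell_lines(self, tag: str) -> "ReferenceLibrary":
        """Sub-library restricted to cell lines carrying ``tag``."""
        keep = [
            i for i, cl in enumerate(self.cell_lines)
            if tag in self.cell_line_tags.get(cl, set())
        ]
        if not keep:
            raise ConfigError(f"no cell line carries tag {tag!r}")
        return ReferenceLibrary(
            gene_universe=list(self.gene_universe),
            scores=self.scores[:, keep].copy(),
            perturbagens=[self.perturbagens[i] for i in keep],
            cell_lines=[self.cell_lines[i] for i in keep],
            cell_line_tags={k: set(v) for k, v in self.cell_line_tags.items()},
        )


def _read_tags(tags_path: str | Path) -> dict[str, set[str]]:
    tags: dict[str, set[str]] = {}
    with open(tags_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{tags_path}:{lineno}: expected 'cell_line<TAB>tag'"
                )
            if parts[0] == "cell_line" and parts[1] == "tag" and lineno == 1:
                continue
            tags.setdefault(parts[0], set()).add(parts[1])
    return tags


def read_reference_library(path: str | Path, tags_path: str | Path | None = None) -> ReferenceLibrary:
    """Read a reference library from long-format TSV
    (``perturbagen  cell_line  gene  score``) or GCT 1.3 text.

    The gene universe is the sorted union of genes seen; a profile
    missing a gene gets score 0 and the total number of imputed entries
    is logged and stored on the returned library.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tags = _read_tags(tags_path) if tags_path is not None else {}
    if first.startswith("#1.3"):
        lib = _read_library_gct(path)
    else:
        lib = _read_library_long(path)
    lib.cell_line_tags.update(tags)
    return lib


def _read_library_long(path: Path) -> ReferenceLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["perturbagen", "cell_line", "gene", "score"]
    if list(df.columns[:4]) != required:
        raise FormatError(
            f"{path}: expected columns {required}, got {list(df.columns[:4])}"
        )
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        row = int(np.argwhere(score.isna().to_numpy())[0][0])
        raise FormatError(
            f"{path}: non-numeric score {df['score'].iat[row]!r} "
            f"(line {row + 2})"
        )
    dup = df.duplicated(subset=["perturbagen", "cell_line", "gene"])
    if dup.any():
        row = int(np.argwhere(dup.to_numpy())[0][0])
        raise FormatError(
            f"{path}: duplicated (perturbagen, cell_line, gene) triple at "
            f"line {row + 2}: "
            f"({df['perturbagen'].iat[row]}, {df['cell_line'].iat[row]}, "
            f"{df['gene'].iat[row]})"
        )
    universe = sorted(df["gene"].unique())
    gene_index = {g: i for i, g in enumerate(universe)}
    pairs = list(dict.fromkeys(zip(df["perturbagen"], df["cell_line"])))
    pair_index = {p: j for j, p in enumerate(pairs)}
    scores = np.zeros((len(universe), len(pairs)))
    filled = np.zeros_like(scores, dtype=bool)
    rows = df["gene"].map(gene_index).to_numpy()
    cols = np.array([pair_index[p] for p in zip(df["perturbagen"], df["cell_line"])])
    scores[rows, cols] = score.to_numpy()
    filled[rows, cols] = True
    n_imputed = int((~filled).sum())
    if n_imputed:
        logger.warning(
            "%s: %d missing (profile, gene) entries imputed as 0", path, n_imputed
        )
    return ReferenceLibrary(
        gene_universe=universe,
        scores=scores,
        perturbagens=[p for p, _ in pairs],
        cell_lines=[c for _, c in pairs],
        n_imputed=n_imputed,
    )


def write_library_long(lib: ReferenceLibrary, path: str | Path,
                       tags_path: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("perturbagen\tcell_line\tgene\tscore\n")
        for j in range(lib.n_profiles):
            pert, cl = lib.perturbagens[j], lib.cell_lines[j]
            for i, g in enumerate(lib.gene_universe):
                fh.write(f"{pert}\t{cl}\t{g}\t{float(lib.scores[i, j])!r}\n")
    if tags_path is not None:
        with open(tags_path, "w") as fh:
            for cl in sorted(lib.cell_line_tags):
                for tag in sorted(lib.cell_line_tags[cl]):
                    fh.write(f"{cl}\t{tag}\n")


# GCT 1.3 text dialect: version line, dimension line, header row, two
# column-metadata rows (pert_id, cell_id), then one data row per gene.
_GCT_COL_META = ("pert_id", "cell_id")


def write_library_gct(lib: ReferenceLibrary, path: str | Path) -> None:
    n_rows, n_cols = len(lib.gene_universe), lib.n_profiles
    col_ids = [f"{p}:{c}" for p, c in zip(lib.perturbagens, lib.cell_lines)]
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{n_rows}\t{n_cols}\t0\t{len(_GCT_COL_META)}\n")
        fh.write("\t".join(["id", *col_ids]) + "\n")
        fh.write("\t".join(["pert_id", *lib.perturbagens]) + "\n")
        fh.write("\t".join(["cell_id", *lib.cell_lines]) + "\n")
        for i, g in enumerate(lib.gene_universe):
            fh.write("\t".join([g, *[repr(float(v)) for v in lib.scores[i]]]) + "\n")


def _read_library_gct(path: Path) -> ReferenceLibrary:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#1.3"):
        raise FormatError(f"{path}: not a GCT 1.3 file")
    try:
        n_rows, n_cols, n_rmeta, n_cmeta = map(int, lines[1].split("\t"))
    except ValueError as exc:
        raise FormatError(f"{path}:2: bad dimension line") from exc
    header = lines[2].split("\t")
    col_meta: dict[str, list[str]] = {}
    for k in range(n_cmeta):
        parts = lines[3 + k].split("\t")
        col_meta[parts[0]] = parts[1 + n_rmeta:]
    for name in _GCT_COL_META:
        if name not in col_meta:
            raise FormatError(f"{path}: missing column metadata row {name!r}")
    data_start = 3 + n_cmeta
    genes: list[str] = []
    values = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        parts = lines[data_start + i].split("\t")
        genes.append(parts[0])
        try:
            values[i] = [float(v) for v in parts[1 + n_rmeta:]]
        except ValueError as exc:
            raise FormatError(
                f"{path}:{data_start + i + 1}: non-numeric score"
            ) from exc
    order = np.argsort(genes, kind="stable")
    return ReferenceLibrary(
        gene_universe=[genes[i] for i in order],
        scores=values[order],
        perturbagens=list(col_meta["pert_id"]),
        cell_lines=list(col_meta["cell_id"]),
    )


# ---------------------------------------------------------------------------
# ConnectionResult

@dataclass(frozen=True)
class ConnectionResult:
    """One compound–signature association.

    ``direction`` is ``"rev"`` for a negative score (profile opposes the
    signature — therapeutic candidate), ``"prog"`` for positive (profile
    mimics it), and ``None`` at exactly zero, which is never significant.
    ``cell_line`` is ``None`` for perturbagen-level aggregates.
    """

    perturbagen: str
    score: float
    p_value: float
    q_value: float
    significant: bool
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.score <= 1.0 + 1e-12:
            raise IntegrityError(f"score {self.score} outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise IntegrityError(f"p-value {self.p_value} outside (0, 1]")
        if self.q_value < self.p_value - 1e-12:
            raise IntegrityError("q-value below p-value")
        if self.score == 0.0 and self.significant:
            raise IntegrityError("zero-score connection cannot be significant")

    @property
    def direction(self) -> str | None:
        if self.score < 0:
            return "rev"
        if self.score > 0:
            return "prog"
        return None


def connections_to_frame(results: Sequence[ConnectionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "perturbagen": [r.perturbagen for r in results],
            "cell_line": [r.cell_line if r.cell_line is not None else "" for r in results],
            "score": [r.score for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "direction": [r.direction if r.direction is not None else "" for r in results],
            "significant": [r.significant for r in results],
        }
    )


def write_connections(results: Sequence[ConnectionResult], path: str | Path) -> None:
    connections_to_frame(results).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run manifest

def write_manifest(path: str | Path, *, seed: int, config: Mapping[str, object],
                   extra: Mapping[str, object] | None = None) -> None:
    """Write the JSON run manifest recording seed, config and version."""
    from . import __version__

    payload: dict[str, object] = {
        "software": "sigdepth",
        "version": __version__,
        "seed": int(seed),
        "config": dict(config),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
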