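"""Readers and writers for the standard formats the pipeline touches.

Formats: FASTA sequences with a two-column CSV population map, square
PHYLIP distance matrices, SplitsTree-dialect NEXUS TAXA/SPLITS/CYCLE
blocks, newick trees (handled in :mod:`ihedge.core`), CSV extinction
profiles and CSV ranking tables, and a small YAML run configuration.

All readers reject malformed input rather than silently repairing it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    DistanceMatrix,
    ExtinctionProfile,
    RankingTable,
    Split,
    TaxonSet,
    WeightedSplitSystem,
)
from .distances import PopulationAlignment
from .indices import iucn_to_pext
from .nnet import CircularOrdering

__all__ = [
    "read_nexus_splits",
    "write_nexus_splits",
    "read_distance_phylip",
    "write_distance_phylip",
    "read_fasta_with_popmap",
    "read_extinction_csv",
    "write_ranking_csv",
    "write_phist_details_csv",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# NEXUS TAXA / SPLITS / CYCLE  (SplitsTree4 dialect, 1-based indices)
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"\[[^\]]*\]")


def _strip_nexus_comments(text: str) -> str:
    return _COMMENT_RE.sub(" ", text)


def _get_block(text: str, name: str) -> str:
    m = re.search(
        rf"BEGIN\s+{name}\s*;(.*?)END\s*;",
        text,
        flags=re.IGNORECASE | re.DOTALL,
    )
    if not m:
        raise ValueError(f"NEXUS file has no {name.upper()} block")
    return m.group(1)


def read_nexus_splits(path: "str | Path") -> tuple[WeightedSplitSystem, CircularOrdering | None]:
    """Read a split system from a NEXUS file with TAXA and SPLITS blocks.

    Taxon indices in the SPLITS matrix are 1-based; each matrix row lists
    a weight followed by the taxon indices of one side, terminated by a
    comma.  A CYCLE statement, if present, is returned as a
    :class:`~ihedge.nnet.CircularOrdering` (0-based), otherwise ``None``.
    """
    text = _strip_nexus_comments(Path(path).read_text())
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError("not a NEXUS file (missing #NEXUS header)")

    taxa_block = _get_block(text, "TAXA")
    m = re.search(r"DIMENSIONS\s+NTAX\s*=\s*(\d+)", taxa_block, re.IGNORECASE)
    if not m:
        raise ValueError("TAXA block missing DIMENSIONS NTAX")
    ntax = int(m.group(1))
    m = re.search(r"TAXLABELS(.*?);", taxa_block, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError("TAXA block missing TAXLABELS")
    labels = re.findall(r"'([^']*)'|(\S+)", m.group(1))
    labels = [a if a else b for a, b in labels]
    if len(labels) != ntax:
        raise ValueError(
            f"TAXLABELS lists {len(labels)} labels but NTAX={ntax}"
        )
    taxa = TaxonSet(labels)

    splits_block = _get_block(text, "SPLITS")
    m = re.search(r"NSPLITS\s*=\s*(\d+)", splits_block, re.IGNORECASE)
    nsplits = int(m.group(1)) if m else None

    ordering = None
    m = re.search(r"CYCLE\s+([\d\s]+);", splits_block, re.IGNORECASE)
    if m:
        cyc = [int(x) - 1 for x in m.group(1).split()]
        ordering = CircularOrdering(tuple(cyc))
        if ordering.n != ntax:
            raise ValueError("CYCLE length does not match NTAX")

    m = re.search(r"MATRIX(.*?);", splits_block, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError("SPLITS block missing MATRIX")
    rows = [r.strip() for r in m.group(1).split(",")]
    rows = [r for r in rows if r]
    splits: list[tuple[Split, float]] = []
    seen: set[Split] = set()
    for row in rows:
        toks = row.split()
        if len(toks) < 2:
            raise ValueError(f"malformed SPLITS matrix row: {row!r}")
        w = float(toks[0])
        side = []
        for t in toks[1:]:
            i = int(t)
            if not 1 <= i <= ntax:
                raise ValueError(f"taxon index {i} out of range 1..{ntax}")
            side.append(i - 1)
        sp = Split.of(frozenset(side), ntax)
        if sp in seen:
            raise ValueError(f"duplicate split in SPLITS matrix: {sp}")
        seen.add(sp)
        splits.append((sp, w))
    if nsplits is not None and len(splits) != nsplits:
        raise ValueError(
            f"SPLITS matrix has {len(splits)} rows but NSPLITS={nsplits}"
        )
    return WeightedSplitSystem(taxa, splits), ordering


def write_nexus_splits(
    system: WeightedSplitSystem,
    path: "str | Path",
    ordering: CircularOrdering | None = None,
) -> None:
    """Write a SplitsTree-readable NEXUS file with TAXA and SPLITS blocks.

    Matrix rows are ordered deterministically: weight descending, then
    lexicographically by side-A membership.
    """
    taxa = system.taxa
    rows = sorted(
        system.splits, key=lambda sw: (-sw[1], tuple(sorted(sw[0].side_a)))
    )
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={taxa.n};", "TAXLABELS"]
    for i, lab in enumerate(taxa, start=1):
        lines.append(f"[{i}] '{lab}'")
    lines += [";", "END;", "", "BEGIN SPLITS;"]
    lines.append(f"DIMENSIONS NTAX={taxa.n} NSPLITS={len(rows)};")
    lines.append("FORMAT LABELS=NO WEIGHTS=YES;")
    if ordering is not None:
        if ordering.n != taxa.n:
            raise ValueError("ordering does not match taxon count")
        lines.append(
            "CYCLE " + " ".join(str(i + 1) for i in ordering.ordering) + ";"
        )
    lines.append("MATRIX")
    for k, (sp, w) in enumerate(rows, start=1):
        side = " ".join(str(i + 1) for i in sorted(sp.side_a))
        lines.append(f"[{k}, size={len(sp.side_a)}]\t{w:.10g}\t{side},")
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix
# ---------------------------------------------------------------------------

def read_distance_phylip(path: "str | Path") -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (label + n floats per row).

    Rows may wrap over multiple lines.  Asymmetry beyond 1e-8 is an
    error, not repaired.
    """
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError("empty PHYLIP file")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise ValueError(f"bad PHYLIP header line: {lines[0]!r}") from None
    toks: list[str] = []
    for ln in lines[1:]:
        toks.extend(ln.split())
    labels: list[str] = []
    values = np.zeros((n, n))
    pos = 0
    for i in range(n):
        if pos >= len(toks):
            raise ValueError(f"PHYLIP matrix truncated at row {i + 1}")
        labels.append(toks[pos])
        pos += 1
        row = toks[pos : pos + n]
        if len(row) < n:
            raise ValueError(f"row {i + 1} has {len(row)} of {n} values")
        try:
            values[i] = [float(x) for x in row]
        except ValueError:
            raise ValueError(f"non-numeric value in row {i + 1}") from None
        pos += n
    if pos != len(toks):
        raise ValueError("trailing tokens after PHYLIP matrix")
    return DistanceMatrix(labels, values)


def write_distance_phylip(D: DistanceMatrix, path: "str | Path") -> None:
    lines = [f"{D.n}"]
    for lab, row in zip(D.labels, D.values):
        lines.append(lab + "\t" + "\t".join(f"{x:.10f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA + population map
# ---------------------------------------------------------------------------

def read_fasta_with_popmap(
    fasta: "str | Path", popmap: "str | Path"
) -> PopulationAlignment:
    """Read an aligned FASTA and group sequences by the population map.

    The map is a two-column CSV ``sequence_id,population`` (an optional
    header line is skipped).  Every FASTA id must be mapped; unmapped ids
    are an error listing the offenders.  Map entries without a FASTA
    record are ignored.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta}")
    mapping: dict[str, str] = {}
    lines = Path(popmap).read_text().splitlines()
    for k, ln in enumerate(lines):
        ln = ln.strip()
        if not ln:
            continue
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 2:
            raise ValueError(f"popmap line {k + 1} is not two columns: {ln!r}")
        if k == 0 and parts[0].lower() in ("id", "sequence_id", "seq_id", "sample"):
            continue
        mapping[parts[0]] = parts[1]
    unmapped = [r.id for r in records if r.id not in mapping]
    if unmapped:
        raise ValueError(f"sequence ids missing from popmap: {unmapped}")
    pops: dict[str, list[str]] = {}
    for r in records:
        pops.setdefault(mapping[r.id], []).append(str(r.seq).upper())
    return PopulationAlignment(pops)


# ---------------------------------------------------------------------------
# Extinction profiles and rankings (CSV)
# ---------------------------------------------------------------------------

def read_extinction_csv(path: "str | Path") -> ExtinctionProfile:
    """Read a per-taxon extinction profile from CSV.

    Two schemas are accepted: ``taxon,pext`` with probabilities in
    [0, 1], or ``taxon,iucn_category`` with Red List categories that are
    converted through the default proxy table (VU=0.1, EN=0.667,
    CR=0.999, EX=1.0).  The second column is treated as categories
    whenever any value fails to parse as a number.
    """
    df = pd.read_csv(path, header=None, comment="#", dtype=str).dropna(how="all")
    if df.shape[1] != 2:
        raise ValueError("extinction profile CSV must have exactly 2 columns")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("taxon", "species", "label"):
        df = df.iloc[1:]
    taxa = [str(x).strip() for x in df.iloc[:, 0]]
    raw = [str(x).strip() for x in df.iloc[:, 1]]
    try:
        vals = [float(x) for x in raw]
    except ValueError:
        vals = [iucn_to_pext(x) for x in raw]
    return ExtinctionProfile(dict(zip(taxa, vals)))


_RANKING_COLUMNS = [
    "taxon", "SH", "HED", "HEDGE", "ihedge_rank", "iteration_picked", "tied",
]


def write_ranking_csv(table: RankingTable, path: "str | Path",
                      rank_column: str = "ihedge_rank") -> None:
    """Write a ranking table as CSV.

    Columns: taxon, SH, HED, HEDGE, the rank column, the iteration at
    which the taxon was picked (empty for non-iterative rankings), and
    the tie flag.
    """
    recs = []
    for r in table.by_rank():
        recs.append({
            "taxon": r.label,
            "SH": r.values.get("SH", ""),
            "HED": r.values.get("HED", ""),
            "HEDGE": r.values.get("HEDGE", ""),
            rank_column: r.rank,
            "iteration_picked": "" if r.iteration_picked is None else r.iteration_picked,
            "tied": int(r.tied),
        })
    cols = _RANKING_COLUMNS[:4] + [rank_column] + _RANKING_COLUMNS[5:]
    pd.DataFrame.from_records(recs)[cols].to_csv(path, index=False)


def write_phist_details_csv(results, path: "str | Path") -> None:
    """Per-pair Phi_ST details (raw values, variance components, p-values)."""
    recs = []
    for (pa, pb), r in sorted(results.items()):
        recs.append({
            "pop1": pa, "pop2": pb,
            "phi_st_raw": r.phi_st,
            "sigma2_among": r.sigma2_a,
            "sigma2_within": r.sigma2_b,
            "n_pairs_used": r.n_pairs_used,
            "undefined": int(r.undefined),
            "p_value": "" if r.p_value is None else r.p_value,
        })
    pd.DataFrame.from_records(recs).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration with the documented defaults.

    ``gamma_alpha`` — gamma shape for the K2P distance (0.5, the
    empirical value for control-region sequences); ``saved_pext`` — the
    near-zero extinction probability given to taxa already prioritized
    during the I-HEDGE iteration; ``weight_threshold`` — minimum split
    weight kept by NeighbourNet; ``permutations`` — Phi_ST permutation
    count; ``seed`` — base seed for everything stochastic.
    """

    gamma_alpha: float | None = 0.5
    saved_pext: float = 0.001
    weight_threshold: float = 1e-6
    permutations: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive or None")
        if not 0.0 <= self.saved_pext <= 1.0:
            raise ValueError("saved_pext must be in [0, 1]")
        if self.weight_threshold < 0:
            raise ValueError("weight_threshold must be >= 0")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
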