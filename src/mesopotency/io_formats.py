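"""Readers and writers for every on-disk artifact, plus the run configuration.

Formats
-------
* expression / beta / Ct matrices: TSV, first column = gene/probe id, header
  row = sample ids, values written with 6 significant digits
* design tables: TSV with columns ``sample``, ``condition``, ``replicate``
* gene sets: GMT (name, description, members, tab separated)
* ChIP peaks: BED3+ with 0-based half-open intervals; an optional 4th column
  names the bound transcription factor
* gene models: TSV with columns ``gene``, ``chrom``, ``strand``, ``tss``,
  ``gene_end`` in 1-based coordinates (converted to 0-based internally)
* signaling cascades: one per line, ``name: A -> B -| C [=> terminal label]``
  where ``->`` is activation (+1) and ``-|`` inhibition (-1)
* run configuration: YAML
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    BetaTable,
    ConfigurationError,
    CtTable,
    DesignError,
    DesignTable,
    ExpressionMatrix,
    ParseError,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# cascade specifications
# ---------------------------------------------------------------------------

@dataclass
class CascadeSpec:
    """An ordered, signed signaling chain.

    ``edge_signs[i]`` is the sign (+1 activation, -1 inhibition) of the edge
    from ``components[i]`` to ``components[i + 1]``. ``terminal_label`` is an
    optional non-gene endpoint such as "Mesoderm Induction".
    """

    name: str
    components: list[str]
    edge_signs: list[int]
    terminal_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ParseError(f"cascade {self.name!r} needs >= 2 components")
        if len(self.edge_signs) != len(self.components) - 1:
            raise ParseError(
                f"cascade {self.name!r}: {len(self.components)} components need "
                f"{len(self.components) - 1} edge signs, got {len(self.edge_signs)}"
            )
        if any(s not in (+1, -1) for s in self.edge_signs):
            raise ParseError(f"cascade {self.name!r}: edge signs must be +1 or -1")
        if any(not c for c in self.components):
            raise ParseError(f"cascade {self.name!r}: empty component symbol")


_EDGE_TOKENS = {"->": +1, "-|": -1}


def parse_cascades(path: str | Path) -> list[CascadeSpec]:
    """Parse a cascade file; grammar ``name: A -> B -| C [=> label]``."""
    specs: list[CascadeSpec] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"line {lineno}: missing 'name:' prefix")
        name, rest = line.split(":", 1)
        terminal = None
        if "=>" in rest:
            rest, terminal = rest.split("=>", 1)
            terminal = terminal.strip()
        tokens = rest.split()
        if len(tokens) < 3:
            raise ParseError(f"line {lineno}: cascade {name.strip()!r} needs >= 2 components")
        components = tokens[0::2]
        edges = tokens[1::2]
        if len(edges) != len(components) - 1:
            raise ParseError(f"line {lineno}: malformed cascade chain")
        signs = []
        for tok in edges:
            if tok not in _EDGE_TOKENS:
                raise ParseError(f"line {lineno}: unknown edge token {tok!r}")
            signs.append(_EDGE_TOKENS[tok])
        specs.append(CascadeSpec(name.strip(), components, signs, terminal))
    return specs


def write_cascades(specs: list[CascadeSpec], path: str | Path) -> None:
    sign_tok = {+1: "->", -1: "-|"}
    lines = []
    for s in specs:
        parts = [s.components[0]]
        for sign, comp in zip(s.edge_signs, s.components[1:]):
            parts += [sign_tok[sign], comp]
        line = f"{s.name}: " + " ".join(parts)
        if s.terminal_label:
            line += f" => {s.terminal_label}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices and design tables
# ---------------------------------------------------------------------------

def read_design_table(path: str | Path) -> DesignTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    return DesignTable(df)


def write_design_table(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def _read_numeric_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at (gene={row!r}, sample={col!r})"
            )
        out[col] = converted
    return out


def read_expression_table(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV intensity/log2 matrix and attach its design.

    Duplicated gene ids are preserved as distinct probe rows. Any non-numeric
    cell (including "NA") is a parse error naming the offending row/column.
    """
    values = _read_numeric_matrix(path)
    design = read_design_table(design_path)
    return ExpressionMatrix(values, design)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_beta_table(
    path: str | Path, design_path: str | Path, probe_map_path: str | Path
) -> BetaTable:
    betas = _read_numeric_matrix(path)
    design = read_design_table(design_path)
    pmap = read_probe_map(probe_map_path)
    return BetaTable(betas, pmap, design)


def write_beta_table(table: BetaTable, path: str | Path) -> None:
    table.betas.to_csv(path, sep="\t", index_label="probe", float_format=_FLOAT_FMT)


def read_probe_map(path: str | Path) -> pd.Series:
    """Probe -> gene mapping TSV with columns ``probe``, ``gene``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe", "gene"} <= set(df.columns):
        raise ParseError(f"{path}: probe map needs columns 'probe' and 'gene'")
    return pd.Series(df["gene"].to_numpy(), index=df["probe"], name="gene")


def write_probe_map(pmap: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"probe": pmap.index, "gene": pmap.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_ct_table(path: str | Path, design_path: str | Path, reference_gene: str) -> CtTable:
    values = _read_numeric_matrix(path)
    design = read_design_table(design_path)
    return CtTable(values, reference_gene, design)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set name: member set}``.

    Members are de-duplicated; empty sets are dropped with a logged warning.
    """
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno} has fewer than 2 fields")
        name = fields[0]
        members = {m for m in fields[2:] if m}
        if not members:
            logger.warning("GMT set %r is empty; dropped", name)
            continue
        sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na"] + sorted(members)) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# peaks (BED) and gene models
# ---------------------------------------------------------------------------

def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read BED3+ peaks (0-based half-open) into columns chrom/start/end/tf."""
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno} has fewer than 3 BED fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
        if start >= end:
            raise ParseError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
        tf = fields[3] if len(fields) > 3 else ""
        rows.append((fields[0], start, end, tf))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])


def write_bed_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene model TSV: gene, chrom, strand, tss, gene_end (1-based).

    Internally coordinates are converted to 0-based positions: ``tss`` is the
    position of the transcription start base and ``gene_end`` the last
    transcribed base (so tss <= gene_end on '+', gene_end <= tss on '-').
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    needed = {"gene", "chrom", "strand", "tss", "gene_end"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: gene model table needs columns {sorted(needed)}")
    if df["strand"].isna().any() or not set(df["strand"]) <= {"+", "-"}:
        raise ParseError(f"{path}: gene model strand must be '+' or '-'")
    out = df.copy()
    out["tss"] = df["tss"].astype(int) - 1
    out["gene_end"] = df["gene_end"].astype(int) - 1
    return out


def write_gene_models(models: pd.DataFrame, path: str | Path) -> None:
    """Write a 0-based in-memory gene model table back to 1-based TSV."""
    out = models.copy()
    out["tss"] = out["tss"].astype(int) + 1
    out["gene_end"] = out["gene_end"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "baseline_condition": "baseline",
    "fdr": 0.05,
    "min_beta_change": 0.25,
    "probe_consistency_min_delta": 0.15,
    "enrichment_min_fold": 1.2,
    "enrichment_max_p": 0.05,
    "n_permutations": 100,
    "seed": 7,
    "k_clusters": 3,
    "exclusion_genes": ["GNAS"],
    "upstream_bp": 10000,
    "downstream_bp": 3000,
    "detection_threshold": 0.05,
    "detection_mode": "any",
    "collapse_rule": "mean",
    "tolerance": 0.0,
    "paths": {},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load the YAML run configuration, filling defaults and validating."""
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must hold a mapping")
        for key, value in loaded.items():
            if key == "paths":
                config["paths"].update(value or {})
            else:
                config[key] = value
    if overrides:
        for key, value in overrides.items():
            if key == "paths":
                config["paths"].update(value)
            else:
                config[key] = value
    _validate_config(config)
    return config


def _validate_config(config: dict) -> None:
    if not (0 <= config["fdr"] <= 1):
        raise ConfigurationError("config key 'fdr' must lie in [0, 1]")
    if not (0 <= config["min_beta_change"] <= 1):
        raise ConfigurationError("config key 'min_beta_change' must lie in [0, 1]")
    if int(config["n_permutations"]) < 1:
        raise ConfigurationError("config key 'n_permutations' must be >= 1")
    if int(config["k_clusters"]) < 2:
        raise ConfigurationError("config key 'k_clusters' must be >= 2")
    if config["detection_mode"] not in ("any", "all"):
        raise ConfigurationError("config key 'detection_mode' must be 'any' or 'all'")


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
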