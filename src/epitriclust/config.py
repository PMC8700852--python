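"""Run configuration: YAML schema, validation, and the all-in-one pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bicluster import (
    DEFAULT_MIN_SUPPORT_FRACTION,
    mine_mark_biclusters,
)
from .coherence import DEFAULT_THETA, build_transactions
from .fpgrowth import minimum_support_from_fraction
from .preprocess import (
    DEFAULT_N_BINS,
    DEFAULT_TARGET_TOTAL,
    MarkTensor,
    build_mark_tensor,
)
from .synthetic import PlantedBlock, PlantedModel
from .tricluster import mine_triclusters, verify_tricluster

log = logging.getLogger("epitriclust")


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs, usually loaded from YAML.

    Exactly one input style must be set: ``tensors`` (pre-built tensor
    TSVs, already normalized) or ``promoters`` + ``manifest`` (raw
    bedGraph signal to preprocess; manifest TSV columns group, mark, path).
    """

    out_dir: str
    tensors: list[str] = field(default_factory=list)
    promoters: str | None = None
    manifest: str | None = None
    n_bins: int = DEFAULT_N_BINS
    theta: float = DEFAULT_THETA
    min_support_fraction: float = DEFAULT_MIN_SUPPORT_FRACTION
    target_total: float = DEFAULT_TARGET_TOTAL
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.theta <= 1:
            raise ConfigError(f"theta must be in (0, 1], got {self.theta}")
        if not 0 < self.min_support_fraction <= 1:
            raise ConfigError(
                "min_support_fraction must be in (0, 1], got "
                f"{self.min_support_fraction}"
            )
        if self.n_bins < 2:
            raise ConfigError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.target_total <= 0:
            raise ConfigError(f"target_total must be > 0, got {self.target_total}")
        has_tensors = bool(self.tensors)
        has_raw = self.promoters is not None or self.manifest is not None
        if has_tensors and has_raw:
            raise ConfigError("give either tensors or promoters+manifest, not both")
        if not has_tensors:
            if self.promoters is None or self.manifest is None:
                raise ConfigError(
                    "inputs must set tensors, or both promoters and manifest"
                )
        if not self.out_dir:
            raise ConfigError("out_dir is required")


_RUN_KEYS = {
    "out_dir",
    "tensors",
    "promoters",
    "manifest",
    "n_bins",
    "theta",
    "min_support_fraction",
    "target_total",
    "seed",
}


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigError(f"{path}: out_dir is required")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def explain_config() -> str:
    """Human-readable description of every run-config key."""
    return "\n".join(
        [
            "Run configuration keys (YAML):",
            "  out_dir               output directory (required)",
            "  tensors               list of tensor TSV paths (already normalized)",
            "  promoters             promoter BED (with manifest, for raw signal)",
            "  manifest              TSV with columns group, mark, path (bedGraph)",
            f"  n_bins                bins per promoter (default {DEFAULT_N_BINS})",
            f"  theta                 coherence threshold in (0,1] (default {DEFAULT_THETA};",
            "                        0.72 is the stricter preset)",
            "  min_support_fraction  minimum support as a fraction of studied",
            f"                        genes (default {DEFAULT_MIN_SUPPORT_FRACTION})",
            f"  target_total          depth-normalization target (default {DEFAULT_TARGET_TOTAL:g})",
            "  seed                  RNG seed (only simulation draws random numbers)",
        ]
    )


def _load_manifest(path) -> list[tuple[str, str, str]]:
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["group", "mark", "path"]:
            raise ConfigError(
                f"{path}: manifest header must be group<TAB>mark<TAB>path"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigError(f"{path}:{lineno}: expected 3 fields")
            rows.append((fields[0], fields[1], fields[2]))
    if not rows:
        raise ConfigError(f"{path}: empty manifest")
    return rows


def load_input_tensors(config: RunConfig) -> dict[str, MarkTensor]:
    """Stage 1: read pre-built tensors or preprocess raw signal."""
    from .io import read_bed, read_bedgraph, read_tensors

    if config.tensors:
        tensors: dict[str, MarkTensor] = {}
        for path in config.tensors:
            for mark, tensor in read_tensors(path).items():
                if mark in tensors:
                    raise ConfigError(f"mark {mark!r} appears in multiple files")
                tensors[mark] = tensor
        return tensors

    promoters = read_bed(config.promoters)
    by_mark: dict[str, list] = {}
    for group, mark, path in _load_manifest(config.manifest):
        by_mark.setdefault(mark, []).append(read_bedgraph(path, group, mark))
    return {
        mark: build_mark_tensor(
            tracks,
            promoters,
            n_bins=config.n_bins,
            target_total=config.target_total,
        )
        for mark, tracks in by_mark.items()
    }


def run_pipeline(config: RunConfig) -> dict:
    """Preprocess -> transactions -> biclusters -> triclusters.

    Writes tensors.tsv (when preprocessing), transactions.tsv,
    biclusters.json, triclusters.json and summary.json under
    ``config.out_dir``.  Deterministic: identical config and inputs give
    byte-identical artifacts.  Returns the summary dict.
    """
    from .io import write_clusters, write_tensors, write_transactions

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        tensors = load_input_tensors(config)
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"stage preprocess: {exc}") from exc
    marks = sorted(tensors)
    if not marks:
        raise RuntimeError("stage preprocess: no tensors loaded")
    genes = tensors[marks[0]].genes
    for mark in marks:
        if tensors[mark].genes != genes:
            raise RuntimeError(
                f"stage preprocess: gene roster of mark {mark!r} differs"
            )
    if not config.tensors:
        write_tensors([tensors[m] for m in marks], out / "tensors.tsv")
    log.info("preprocess: %d marks, %d groups, %d genes, %d bins",
             len(marks), len(tensors[marks[0]].groups), len(genes),
             tensors[marks[0]].n_bins)

    try:
        transactions = {
            mark: build_transactions(tensors[mark], config.theta) for mark in marks
        }
    except ValueError as exc:
        raise RuntimeError(f"stage transactions: {exc}") from exc
    write_transactions(
        [t for mark in marks for t in transactions[mark]],
        out / "transactions.tsv",
    )
    n_items = sum(len(t.items) for ts in transactions.values() for t in ts)
    log.info("transactions: %d items across %d marks", n_items, len(marks))

    min_support = minimum_support_from_fraction(
        len(genes), config.min_support_fraction
    )
    try:
        biclusters = {
            mark: mine_mark_biclusters(transactions[mark], min_support)
            for mark in marks
        }
    except ValueError as exc:
        raise RuntimeError(f"stage biclusters: {exc}") from exc
    flat_bics = [b for mark in marks for b in biclusters[mark]]
    write_clusters(flat_bics, out / "biclusters.json", tensors=tensors)
    log.info("biclusters: %d (min_support=%d)", len(flat_bics), min_support)

    if len(marks) < 2:
        raise RuntimeError("stage triclusters: need tensors for >= 2 marks")
    try:
        triclusters = mine_triclusters(biclusters, min_support)
    except ValueError as exc:
        raise RuntimeError(f"stage triclusters: {exc}") from exc
    for t in triclusters:
        report = verify_tricluster(t, tensors, config.theta)
        if not report.passed:  # pragma: no cover - internal guard
            raise RuntimeError(
                f"stage triclusters: mined cluster failed recomputation:\n{report}"
            )
    write_clusters(triclusters, out / "triclusters.json", tensors=tensors)
    log.info("triclusters: %d", len(triclusters))

    summary = {
        "n_marks": len(marks),
        "n_groups": len(tensors[marks[0]].groups),
        "n_genes": len(genes),
        "n_bins": tensors[marks[0]].n_bins,
        "theta": config.theta,
        "min_support": min_support,
        "n_biclusters": len(flat_bics),
        "n_triclusters": len(triclusters),
        "fold_ratios": [
            round(t.support / len(genes), 6) for t in triclusters
        ],
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


# ----------------------------------------------------------- model configs


_MODEL_KEYS = {
    "groups",
    "marks",
    "genes",
    "n_genes",
    "n_bins",
    "blocks",
    "template_sd",
    "noise_sd",
    "background_rate",
    "seed",
}


def load_model_config(path) -> PlantedModel:
    """Planted-model YAML -> PlantedModel.

    ``genes`` may be an explicit list or replaced by ``n_genes`` (ids are
    then g0000..).  Each block is a mapping with marks, groups and genes
    lists; a block's genes may also be a two-element [start, stop) range
    into the gene roster.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {k: raw[k] for k in raw if k not in ("n_genes", "blocks", "genes")}
    if "genes" in raw:
        kwargs["genes"] = list(raw["genes"])
    elif "n_genes" in raw:
        kwargs["genes"] = [f"g{i:04d}" for i in range(int(raw["n_genes"]))]
    model = PlantedModel(**kwargs)
    blocks = []
    for i, b in enumerate(raw.get("blocks", [])):
        try:
            genes = b["genes"]
            if (
                isinstance(genes, list)
                and len(genes) == 2
                and all(isinstance(g, int) for g in genes)
            ):
                genes = model.genes[genes[0] : genes[1]]
            blocks.append(
                PlantedBlock(
                    marks=frozenset(b["marks"]),
                    groups=frozenset(b["groups"]),
                    genes=frozenset(genes),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: block {i}: {exc}") from exc
    model.blocks = blocks
    model.__post_init__()
    return model
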