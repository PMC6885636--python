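"""End-to-end orchestration of the ensemble-comparison stages.

A run is described by a single TOML config naming the condition
ensembles (first or flagged one is the reference / wild type), an
optional reference structure for RMSD series, contact and dCNA
parameters, per-condition equilibrated frame windows, and an optional
assay summary CSV.  ``run_pipeline`` executes RMSD, pooled PCA with
per-condition projections, contact probabilities, per-mutant difference
networks, community detection and coarse-graining, and assay reduction,
writing every artifact plus a manifest (inputs, parameters, seed,
output hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gcensemble import __version__
from gcensemble.assay_stats import reduce_table
from gcensemble.contact_analysis import ContactParams, contact_probability
from gcensemble.dcna import (
    coarse_grain,
    detect_communities,
    difference_network,
    export_visualization,
)
from gcensemble.ensemble_pca import fit_pca, project_ensemble
from gcensemble.structure_io import parse_selection, read_pdb_models, select
from gcensemble.superpose import rmsd_to_reference

__all__ = ["ConditionConfig", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass(frozen=True)
class ConditionConfig:
    label: str
    path: Path
    frame_window: tuple[int, int] | None = None
    reference: bool = False


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    conditions: list[ConditionConfig]
    output_dir: Path
    selection: str = "backbone"
    contact_params: ContactParams = field(default_factory=ContactParams)
    dcna_threshold: float = 0.1
    edge_min_probability: float = 0.5
    reference_structure: Path | None = None
    assay_table: Path | None = None
    wildtype_label: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise ConfigError("condition labels must be unique")
        n_ref = sum(c.reference for c in self.conditions)
        if n_ref > 1:
            raise ConfigError("at most one condition may be marked reference")
        if n_ref == 0 and self.conditions:
            self.conditions[0] = ConditionConfig(
                label=self.conditions[0].label,
                path=self.conditions[0].path,
                frame_window=self.conditions[0].frame_window,
                reference=True,
            )
        for c in self.conditions:
            if not Path(c.path).exists():
                raise ConfigError(f"ensemble path does not exist: {c.path}")
        for p in (self.reference_structure, self.assay_table):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")

    @property
    def reference(self) -> ConditionConfig:
        return next(c for c in self.conditions if c.reference)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        root = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else root / p

        conditions = [
            ConditionConfig(
                label=entry["label"],
                path=resolve(entry["path"]),
                frame_window=tuple(entry["frame_window"]) if "frame_window" in entry else None,
                reference=bool(entry.get("reference", False)),
            )
            for entry in raw.get("conditions", [])
        ]
        if not conditions:
            raise ConfigError("config lists no conditions")
        contact = raw.get("contact", {})
        dcna = raw.get("dcna", {})
        return cls(
            conditions=conditions,
            output_dir=resolve(raw.get("output_dir", "gcensemble_out")),
            selection=raw.get("selection", "backbone"),
            contact_params=ContactParams(
                cutoff=float(contact.get("cutoff", 4.5)),
                min_separation=int(contact.get("min_separation", 3)),
                stride=int(contact.get("stride", 1)),
            ),
            dcna_threshold=float(dcna.get("threshold", 0.1)),
            edge_min_probability=float(dcna.get("edge_min_probability", 0.5)),
            reference_structure=resolve(raw["reference_structure"])
            if "reference_structure" in raw else None,
            assay_table=resolve(raw["assay_table"]) if "assay_table" in raw else None,
            wildtype_label=raw.get("wildtype_label", "WT"),
            seed=int(raw.get("seed", 0)),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # '.' decimal separator and LF endings make outputs bit-comparable
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "selection": config.selection,
        "parameters": {
            "contact": {
                "cutoff": config.contact_params.cutoff,
                "min_separation": config.contact_params.min_separation,
                "stride": config.contact_params.stride,
            },
            "dcna_threshold": config.dcna_threshold,
            "edge_min_probability": config.edge_min_probability,
        },
        "inputs": {c.label: str(c.path) for c in config.conditions},
        "stages": {},
        "artifacts": {},
        # stages whose outputs are bit-reproducible given identical inputs
        "deterministic_stages": ["rmsd", "pca", "contacts", "dcna", "assay"],
    }

    def record(stage: str, path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, []).append(str(path.relative_to(out)))

    stage = "load"
    try:
        ensembles = {
            c.label: read_pdb_models(c.path, label=c.label) for c in config.conditions
        }
        windows = {c.label: c.frame_window for c in config.conditions}
        sel_kwargs = parse_selection(config.selection)
        ref_label = config.reference.label

        stage = "rmsd"
        if config.reference_structure is not None:
            reference = read_pdb_models(config.reference_structure, label="reference")
            for label, ens in ensembles.items():
                sel = select(ens.topology, **sel_kwargs)
                ref_sel = select(reference.topology, **sel_kwargs)
                series = rmsd_to_reference(ens, reference, sel, ref_sel)
                path = out / f"rmsd_{_safe(label)}.csv"
                _write_csv(
                    pd.DataFrame(
                        {"frame": series.frame_indices, "rmsd_A": series.rmsd}
                    ),
                    path,
                )
                record("rmsd", path)

        stage = "pca"
        first = ensembles[config.conditions[0].label]
        selection = select(first.topology, **sel_kwargs)
        model = fit_pca(
            list(ensembles.values()),
            selection,
            frame_windows=[windows[label] for label in ensembles],
        )
        path = out / "pca_model.json"
        path.write_text(
            json.dumps(
                {
                    "selection": model.selection_description,
                    "eigenvalues_A2": model.eigenvalues[:10].tolist(),
                    "variance_fractions": model.variance_fractions[:10].tolist(),
                },
                indent=2,
            )
            + "\n"
        )
        record("pca", path)
        rows = []
        for label, ens in ensembles.items():
            projections = project_ensemble(model, ens, frame_window=windows[label])
            for i, (pc1, pc2) in enumerate(projections.points):
                rows.append({"condition": label, "frame": i, "pc1": pc1, "pc2": pc2})
        path = out / "pca_projections.csv"
        _write_csv(pd.DataFrame(rows), path)
        record("pca", path)

        stage = "contacts"
        maps = {}
        for label, ens in ensembles.items():
            windowed = ens.subset(windows[label])
            maps[label] = contact_probability(windowed, config.contact_params)
            path = out / f"contacts_{_safe(label)}.csv"
            _write_csv(pd.DataFrame(maps[label].to_records()), path)
            record("contacts", path)

        stage = "dcna"
        partition = None
        try:
            partition = detect_communities(
                maps[ref_label], config.edge_min_probability
            )
        except ValueError:
            logger.warning("no persistent contacts; skipping community detection")
        if partition is not None:
            path = out / "communities.csv"
            _write_csv(
                pd.DataFrame(
                    [
                        {"chain": r[0], "resid": r[1], "community": c}
                        for r, c in sorted(partition.assignment.items())
                    ]
                ),
                path,
            )
            record("dcna", path)
        for label, cmap in maps.items():
            if label == ref_label:
                continue
            network = difference_network(maps[ref_label], cmap, config.dcna_threshold)
            path = out / f"dcna_{_safe(label)}.csv"
            _write_csv(
                pd.DataFrame(network.to_records(maps[ref_label], cmap)), path
            )
            record("dcna", path)
            viz = out / f"dcna_{_safe(label)}.pml"
            export_visualization(network, ensembles[ref_label], viz)
            record("dcna", viz)
            record("dcna", viz.with_suffix(".csv"))
            if partition is not None:
                full = partition.extended_to(network.residues())
                coarse = coarse_grain(network, full)
                path = out / f"coarse_{_safe(label)}.csv"
                _write_csv(
                    pd.DataFrame(
                        [
                            {"community_a": a, "community_b": b, "net_df": float(w)}
                            for (a, b), w in sorted(coarse.weights.items())
                        ]
                    ),
                    path,
                )
                record("dcna", path)

        stage = "assay"
        if config.assay_table is not None:
            table = pd.read_csv(config.assay_table)
            derived = reduce_table(
                table.to_dict("records"), wildtype_label=config.wildtype_label
            )
            path = out / "assay_derived.csv"
            _write_csv(pd.DataFrame(derived), path)
            record("assay", path)
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _safe(label: str) -> str:
    return "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in label)
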