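"""End-to-end runs tying the stages into the two pipelines.

``run_pipeline`` executes thermodynamics → normalization (the proposed
control-probe method or the conventional baseline) → the requested
evaluations, writing TSV/BED outputs plus a JSON manifest (package
version, parameters, input checksums).  Configuration is a single
declarative mapping (typically loaded from YAML), so a run is
reproducible from its manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import baseline as _baseline
from . import evaluate as _evaluate
from . import io as _io
from . import normalize as _normalize
from .thermo import NNParameterTable, delta_g37_many, load_parameter_table

__all__ = ["run_pipeline", "species_signal_from_matrix", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def species_signal_from_matrix(
    matrix: pd.DataFrame, chips: pd.DataFrame
) -> pd.DataFrame:
    """Per-species mean probe signal from a probes × chips matrix."""
    out = {}
    for species, grp in chips.groupby("species", sort=True):
        cols = [c for c in grp["chip_id"] if c in matrix.columns]
        out[species] = matrix[cols].mean(axis=1)
    return pd.DataFrame(out)


def _ai_from_baseline(matrix: pd.DataFrame, chips: pd.DataFrame) -> pd.DataFrame:
    """Express baseline-normalized signal on the AI (ln) scale per species."""
    sig = species_signal_from_matrix(matrix, chips)
    frames = []
    for species in sig.columns:
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": sig.index,
                    "species": species,
                    "ai": np.log(sig[species].to_numpy()),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: Mapping | str | Path) -> dict:
    """Execute a configured run; returns {output name: path}.

    Config keys (paths are relative to the config file when a path is
    given): ``probes_bed``, ``probes_seq``, ``intensities``, ``chips``,
    ``out_dir``, ``method`` (``proposed`` | ``baseline``),
    ``reference_species``, ``test_species`` (optional, enables the
    deletion scan), ``evaluations`` (subset of ``conserved``,
    ``deletions``), plus optional ``per_chip``, ``robust``,
    ``nn_table``, ``target_mean``, ``bandwidth_bp``, ``deletion_scan``
    parameter mapping, and ``alpha_fw``.
    """
    base = Path(".")
    if not isinstance(config, Mapping):
        cfg_path = Path(config)
        base = cfg_path.parent
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)

    def _path(key):
        return base / cfg[key]

    out_dir = base / cfg["out_dir"]
    out_dir.mkdir(parents=True, exist_ok=True)
    method = cfg.get("method", "proposed")
    if method not in ("proposed", "baseline"):
        raise ValueError(f"unknown method {method!r}")
    outputs: dict[str, Path] = {}
    try:
        stage = "read inputs"
        probes = _io.read_probes(_path("probes_bed"), _path("probes_seq"))
        intensities = _io.read_intensities(_path("intensities"))
        chips = _io.read_chips(_path("chips"))

        stage = "thermo"
        table = (
            load_parameter_table(base / cfg["nn_table"])
            if cfg.get("nn_table")
            else NNParameterTable.unified()
        )
        dg = pd.Series(
            delta_g37_many(probes["sequence"].tolist(), table),
            index=probes["probe_id"],
            name="dg37",
        )
        outputs["dg37"] = out_dir / "dg37.tsv"
        dg.rename_axis("probe_id").reset_index().to_csv(
            outputs["dg37"], sep="\t", index=False
        )

        stage = "normalize" if method == "proposed" else "baseline"
        if method == "proposed":
            ai, fits = _normalize.normalize_experiment(
                intensities,
                chips,
                probes,
                dg,
                per_chip=bool(cfg.get("per_chip", False)),
                robust=bool(cfg.get("robust", False)),
            )
            outputs["fits"] = out_dir / "fits.tsv"
            fits.to_csv(outputs["fits"], sep="\t", index=False)
        else:
            matrix = intensities.pivot(
                index="probe_id", columns="chip_id", values="intensity"
            )
            if matrix.isna().any().any():
                raise ValueError("intensity matrix has missing cells")
            norm = _baseline.baseline_pipeline(
                matrix,
                probes,
                target_mean=float(cfg.get("target_mean", 500.0)),
                bandwidth_bp=int(cfg.get("bandwidth_bp", 50)),
                smooth=bool(cfg.get("smooth", True)),
            )
            outputs["baseline_matrix"] = out_dir / "baseline_normalized.tsv"
            norm.to_csv(outputs["baseline_matrix"], sep="\t")
            ai = _ai_from_baseline(norm, chips)
        outputs["ai"] = out_dir / "ai.tsv"
        ai.to_csv(outputs["ai"], sep="\t", index=False)

        evaluations = cfg.get("evaluations", [])
        if "conserved" in evaluations:
            stage = "conserved"
            frames = []
            for species, grp in ai.groupby("species", sort=True):
                res = _evaluate.conserved_gene_test(
                    grp, probes, alpha_fw=float(cfg.get("alpha_fw", 0.05))
                )
                res.insert(0, "species", species)
                frames.append(res)
            outputs["conserved"] = out_dir / "conserved_genes.tsv"
            pd.concat(frames, ignore_index=True).to_csv(
                outputs["conserved"], sep="\t", index=False
            )
        if "deletions" in evaluations:
            stage = "deletions"
            test_sp, ref_sp = cfg["test_species"], cfg["reference_species"]
            track = _evaluate.ratio_track(
                ai[ai["species"] == test_sp],
                ai[ai["species"] == ref_sp],
                probes[probes["category"] == "target"],
            )
            outputs["ratio_track"] = out_dir / "ratio_track.tsv"
            track.to_csv(outputs["ratio_track"], sep="\t", index=False)
            scan_kw = dict(cfg.get("deletion_scan", {}))
            calls = _evaluate.deletion_scan(track, **scan_kw)
            outputs["deletions"] = out_dir / "deletions.bed"
            calls[["chromosome", "start", "end", "n_probes", "mean_ratio"]].to_csv(
                outputs["deletions"], sep="\t", header=False, index=False
            )

        stage = "manifest"
        manifest_path = out_dir / "manifest.json"
        _io.write_manifest(
            manifest_path,
            params={k: v for k, v in cfg.items() if k != "out_dir"} | {"method": method},
            inputs={
                k: _path(k)
                for k in ("probes_bed", "probes_seq", "intensities", "chips")
            },
            outputs=outputs,
        )
        outputs["manifest"] = manifest_path
        return {k: str(v) for k, v in outputs.items()}
    except Exception as exc:
        for p in outputs.values():
            Path(p).unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
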