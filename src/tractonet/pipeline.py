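"""End-to-end study workflow: connectomes -> indices -> statistics.

:func:`run_full_analysis` turns a set of per-subject connectomes plus a
cohort table into topology profiles, density-controlled group comparisons
with false-nondiscovery correction, cognition-network partial
correlations and strong-correlation count matrices, all written as TSV
with a machine-readable run manifest.  Deterministic under a fixed
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .connectome import Connectome
from .correlation import correlate_cohort
from .inference import compare_groups
from .synthetic import CohortSpec, make_cohort
from .topology import TopologyProfile, global_indices

__all__ = ["RunConfig", "run_full_analysis", "profiles_from_connectomes"]

logger = logging.getLogger(__name__)

_TSV_PREAMBLE = (
    "# units: dimensionless edge weights; 0-based voxel indices; half-open voxel boxes\n"
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str
    connectome_dir: str | None = None  # directory of per-subject CSV matrices
    cohort_csv: str | None = None
    cohort_spec: CohortSpec | None = None  # simulate when no inputs given
    covariate: str = "education"
    r_threshold: float = 0.50
    z_threshold: float = 0.55
    alpha: float = 0.05
    null_realizations: int = 20
    correction: str = "grenander"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_threshold", "z_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def digest(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "cohort_spec"}
        if self.cohort_spec is not None:
            spec = dataclasses.asdict(self.cohort_spec)
            spec["strength_corr"] = {f"{g}/{m}": v for (g, m), v in spec["strength_corr"].items()}
            payload["cohort_spec"] = spec
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def profiles_from_connectomes(
    connectomes: Mapping[str, Connectome],
    null_realizations: int = 20,
    seed: int = 0,
) -> dict[str, TopologyProfile]:
    """Topology profiles (with small-worldness) for every subject."""
    profiles = {}
    for k, (sid, c) in enumerate(sorted(connectomes.items())):
        profiles[sid] = global_indices(
            c, small_world_realizations=null_realizations, seed=seed + k
        )
    return profiles


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with path.open("w") as fh:
        fh.write(_TSV_PREAMBLE)
        df.to_csv(fh, sep="\t", index=False)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole workflow and write all result tables.

    Returns a bundle with the in-memory profiles, comparison and
    correlation frames, count matrices and the manifest dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.connectome_dir is not None and config.cohort_csv is not None:
        cohort = pd.read_csv(config.cohort_csv)
        connectomes = {}
        for sid in cohort["subject_id"].astype(str):
            path = Path(config.connectome_dir) / f"{sid}.csv"
            if not path.exists():
                raise FileNotFoundError(f"no connectome for subject {sid}: {path}")
            connectomes[sid] = Connectome.from_csv(path)
    elif config.cohort_spec is not None:
        spec = config.cohort_spec
        if spec.seed != config.seed:
            spec = dataclasses.replace(spec, seed=config.seed)
        connectomes, cohort = make_cohort(spec)
    else:
        raise ValueError("provide connectome_dir + cohort_csv, or a cohort_spec")

    cohort_ids = set(cohort["subject_id"].astype(str))
    missing = sorted(cohort_ids - set(connectomes)) + sorted(set(connectomes) - cohort_ids)
    if missing:
        raise ValueError(f"subject mismatch between connectomes and cohort table: {missing}")

    logger.info("computing topology profiles for %d subjects", len(connectomes))
    profiles = profiles_from_connectomes(
        connectomes, null_realizations=config.null_realizations, seed=config.seed
    )
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for sid, prof in profiles.items():
        prof.to_tsv(prof_dir / f"{sid}.tsv")

    global_cmp = compare_groups(profiles, cohort, scope="global", method=config.correction)
    local_cmp = compare_groups(profiles, cohort, scope="local", method=config.correction)
    _write_tsv(global_cmp, out / "comparisons_global.tsv")
    _write_tsv(local_cmp, out / "comparisons_local.tsv")

    global_corr, _ = correlate_cohort(
        profiles, cohort, scope="global", covariate=config.covariate,
        z_threshold=config.z_threshold,
    )
    # local correlations over the nodes with corrected significant strength
    # differences between the smallest PD group and controls (the focal
    # question); falls back to all nodes when none are significant
    sig = local_cmp[
        (local_cmp["index"] == "strength")
        & (local_cmp["group_a"] == "control")
        & (local_cmp["p_adj"] < config.alpha)
    ]
    if "pd_mi" in set(sig["group_b"]):
        sig = sig[sig["group_b"] == "pd_mi"]
    sig_nodes = list(dict.fromkeys(sig["node"])) or None
    local_corr, counts = correlate_cohort(
        profiles, cohort, scope="local", covariate=config.covariate,
        nodes=sig_nodes, r_threshold=config.r_threshold,
    )
    _write_tsv(global_corr, out / "correlations_global.tsv")
    _write_tsv(local_corr, out / "correlations_local.tsv")
    for group, (matrix, total) in counts.items():
        matrix.to_csv(out / f"strong_counts_{group}.tsv", sep="\t")
    cohort.to_csv(out / "cohort.csv", index=False)

    manifest = {
        "tool": "tractonet",
        "version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
        "covariate": config.covariate,
        "n_subjects": len(connectomes),
        "groups": cohort["group"].value_counts().to_dict(),
        "significant_strength_nodes": sig_nodes or [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "profiles": profiles,
        "cohort": cohort,
        "comparisons_global": global_cmp,
        "comparisons_local": local_cmp,
        "correlations_global": global_corr,
        "correlations_local": local_corr,
        "counts": counts,
        "manifest": manifest,
    }
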