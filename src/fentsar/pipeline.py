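"""End-to-end orchestration: synthetic pools -> descriptors / contacts /
volumes -> SAR fits and score reweighting, with a reproducibility manifest.

A pipeline run is a pure function of (config, seed): the manifest records
sha256 hashes of every output so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import contact_frequencies, evaluate_general_features, ionic_persistence
from .core import ValidationError
from .descriptors import descriptor_summary
from .rescoring import optimal_score_table, reweight_components, score_affinity_correlation
from .sar import quadratic_fit, two_segment_fit
from .synthetic import SARSpec, ScoreSpec, SyntheticSpec, generate_pool, generate_sar_table, generate_score_table
from .volumes import combined_volume, dynamic_volume

__all__ = ["RunManifest", "SchemaError", "run_pipeline"]


class SchemaError(ValidationError):
    """Configuration does not match the pipeline schema."""


_TOP_KEYS = {"seed", "derivatives", "sar", "scores", "stages"}
_DERIVATIVE_KEYS = {
    "id", "n_replicas", "tail_ns", "per_ns", "run_length_ns",
    "saltbridge_presence", "lock_mean", "lock_sd", "helix_sigma",
}
_STAGES = ("descriptors", "contacts", "volumes", "sar", "rescore")


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "config": self.config,
            "outputs": self.outputs,
            "hashes": self.hashes,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Check configuration keys before any compute; returns a filled copy."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
    out = dict(config)
    out.setdefault("seed", 0)
    out.setdefault("derivatives", [{"id": "SYN01"}, {"id": "SYN02"}])
    out.setdefault("sar", {})
    out.setdefault("scores", {})
    out.setdefault("stages", list(_STAGES))
    for stage in out["stages"]:
        if stage not in _STAGES:
            raise SchemaError(f"unknown stage {stage!r}")
    for d in out["derivatives"]:
        bad = set(d) - _DERIVATIVE_KEYS
        if bad:
            raise SchemaError(f"unknown derivative keys: {sorted(bad)}")
        if "id" not in d:
            raise SchemaError("every derivative needs an 'id'")
    return out


def _write_csv(df: pd.DataFrame, path: Path, stage: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fentsar {__version__} stage={stage} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute the configured stages in dependency order.

    Pools are generated synthetically per derivative (seeded deterministically
    from the top-level seed), descriptors/contacts/volumes are tabulated, and
    the SAR and rescoring analyses run on generated tables with their ground
    truth stored beside the fits.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(seed=seed, config=config, version=__version__)
    children = np.random.SeedSequence(seed).spawn(len(config["derivatives"]) + 2)

    pools = {}
    schemes = {}
    role_map = None
    for child, dcfg in zip(children, config["derivatives"]):
        kwargs = {k: v for k, v in dcfg.items() if k != "id"}
        spec = SyntheticSpec(
            seed=int(child.generate_state(1)[0] % (2**31)),
            derivative_id=dcfg["id"],
            **kwargs,
        )
        sp = generate_pool(spec)
        pools[dcfg["id"]] = sp.pool
        schemes[dcfg["id"]] = sp.scheme
        role_map = sp.role_map
        truth_path = outdir / f"ground_truth_{dcfg['id']}.json"
        truth_path.write_text(json.dumps(sp.truth, indent=1, sort_keys=True))
        manifest.outputs[f"ground_truth_{dcfg['id']}"] = truth_path.name

    stages = config["stages"]
    if "descriptors" in stages:
        table = descriptor_summary(pools, role_map, schemes)
        path = outdir / "descriptors.csv"
        _write_csv(table, path, "descriptors", seed)
        manifest.outputs["descriptors"] = path.name

    if "contacts" in stages:
        parts = []
        gf_all = {}
        for did, pool in pools.items():
            ft = contact_frequencies(pool, schemes[did], role_map)
            ft.insert(0, "derivative_id", did)
            parts.append(ft)
            ion = ionic_persistence(pool, role_map, schemes[did])
            gfs = evaluate_general_features(ft, ion, schemes[did])
            gf_all[did] = {
                name: {"value": g.value, "evidence": g.evidence}
                for name, g in gfs.items()
            }
        path = outdir / "contacts.csv"
        _write_csv(pd.concat(parts, ignore_index=True), path, "contacts", seed)
        manifest.outputs["contacts"] = path.name
        gf_path = outdir / "general_features.json"
        gf_path.write_text(json.dumps(gf_all, indent=1, sort_keys=True))
        manifest.outputs["general_features"] = gf_path.name

    if "volumes" in stages:
        rows = []
        for did, pool in pools.items():
            for fragment in schemes[did].fragments:
                rec = dynamic_volume(pool, schemes[did], fragment)
                rows.append(
                    {
                        "derivative_id": did,
                        "fragment": fragment,
                        "backend": rec.backend,
                        "dynamic_volume": rec.dynamic_volume,
                    }
                )
            rows.append(
                {
                    "derivative_id": did,
                    "fragment": "n_chain+anilide_aromatic",
                    "backend": "classical_ese",
                    "dynamic_volume": combined_volume(pool, schemes[did]),
                }
            )
        path = outdir / "volumes.csv"
        _write_csv(pd.DataFrame(rows), path, "volumes", seed)
        manifest.outputs["volumes"] = path.name

    if "sar" in stages:
        sar_seed = int(children[-2].generate_state(1)[0] % (2**31))
        sar_spec = SARSpec(seed=sar_seed, **config["sar"])
        table, truth = generate_sar_table(sar_spec)
        ts = two_segment_fit(table["volume"], table["pic50"])
        results = {
            "truth": truth,
            "two_segment": {
                "breakpoint": ts.breakpoint,
                "ascending_slope": ts.ascending_slope,
                "descending_slope": ts.descending_slope,
                "sse": ts.sse,
                "single_line": ts.single_line,
            },
        }
        qf = quadratic_fit(table["volume"], table["pic50"])
        results["quadratic"] = {
            "a": qf.a, "b": qf.b, "c": qf.c, "r": qf.r, "vertex": qf.vertex,
        }
        path = outdir / "sar.json"
        path.write_text(json.dumps(results, indent=1, sort_keys=True))
        manifest.outputs["sar"] = path.name
        sar_csv = outdir / "sar_table.csv"
        _write_csv(table, sar_csv, "sar", seed)
        manifest.outputs["sar_table"] = sar_csv.name

    if "rescore" in stages:
        score_seed = int(children[-1].generate_state(1)[0] % (2**31))
        score_spec = ScoreSpec(seed=score_seed, **config["scores"])
        table, pic50, truth = generate_score_table(score_spec)
        opt = optimal_score_table(table, {score_spec.function: score_spec.direction})
        scores = opt.set_index("derivative_id")["score"]
        r, n = score_affinity_correlation(scores, pic50)
        comp = (
            table.groupby("derivative_id")[list(score_spec.component_weights)]
            .mean()
            .loc[pic50.index]
        )
        rw = reweight_components(comp, pic50)
        results = {
            "truth": truth,
            "optimal_score_correlation": {"r": r, "n": n},
            "reweight": {
                "weights": dict(zip(rw.component_names, map(float, rw.weights))),
                "intercept": rw.intercept,
                "internal_r": rw.internal_r,
                "n": rw.n,
            },
        }
        path = outdir / "rescore.json"
        path.write_text(json.dumps(results, indent=1, sort_keys=True))
        manifest.outputs["rescore"] = path.name

    for key, name in manifest.outputs.items():
        manifest.hashes[key] = _sha256(outdir / name)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest.to_json_dict(), indent=1, sort_keys=True)
    )
    return manifest
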