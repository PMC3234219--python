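"""Orchestration: bundled-fixture reproduction and the multi-stage pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__, assay, assoc, burden, catalog, ld
from .errors import ConfigurationError, IntegrityError

log = logging.getLogger("regulaburden")

FIXTURE_FILES = {
    "cohorts": "lipg_cohorts.tsv",
    "rare_variants": "lipg_rare_variants.tsv",
    "common_variants": "lipg_common_variants.tsv",
    "carriers": "lipg_carriers.tsv",
    "functional_calls": "lipg_functional_calls.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture file."""
    return Path(resources.files("regulaburden.data") / name)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def verify_fixtures() -> dict[str, str]:
    """Check bundled fixtures against the recorded digests.

    Returns {filename: digest}; raises IntegrityError on mismatch.
    """
    manifest = json.loads(fixture_path("checksums.json").read_text())
    digests = {}
    for fname, expected in manifest.items():
        actual = _sha256(fixture_path(fname))
        if actual != expected:
            raise IntegrityError(f"fixture {fname} digest mismatch (tampered?)")
        digests[fname] = actual
    return digests


@dataclass
class RunManifest:
    inputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    parameters: dict = field(default_factory=dict)
    package_version: str = __version__
    seeds: dict[str, int] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, status: str, **info) -> None:
        self.stages.append({"stage": stage, "status": status, **info})

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "inputs": self.inputs,
                    "parameters": self.parameters,
                    "package_version": self.package_version,
                    "seeds": self.seeds,
                    "stages": self.stages,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def load_bundled_inputs():
    """Load the bundled catalog, carriers and functional calls."""
    verify_fixtures()
    cohorts = catalog.load_cohorts(fixture_path(FIXTURE_FILES["cohorts"]))
    rare = catalog.load_catalog(fixture_path(FIXTURE_FILES["rare_variants"]), cohorts)
    common = catalog.load_catalog(fixture_path(FIXTURE_FILES["common_variants"]), cohorts)
    carriers = catalog.CarrierTable.load(fixture_path(FIXTURE_FILES["carriers"]))
    calls = assay.load_calls(fixture_path(FIXTURE_FILES["functional_calls"]))
    return cohorts, rare, common, carriers, calls


def reproduce_lipg(sidedness: str = "two") -> pd.DataFrame:
    """One-command reproduction of the bundled burden analysis.

    Emits one row per collapsing test: undirected, both directional tests,
    and both exclusivity-filtered directional tests, with de-duplicated
    carrier counts and exact p-values.
    """
    cohorts, rare, _common, carriers, calls = load_bundled_inputs()
    carriers.validate_against(rare)
    results = [burden.cast(rare, carriers, cohorts, sidedness=sidedness)]
    for exclusive in (False, True):
        for direction in ("decrease", "increase"):
            results.append(
                burden.directional_cast(
                    rare, carriers, calls, direction,
                    exclusive=exclusive, cohorts=cohorts, sidedness=sidedness,
                )
            )
    rows = []
    for r in results:
        rows.append(
            {
                "test": r.test_name,
                "direction": r.direction,
                "exclusive": r.exclusive,
                "carriers_high": r.table.a,
                "carriers_low": r.table.c,
                "n_high": r.table.n1,
                "n_low": r.table.n2,
                "n_variants": len(r.variants_used),
                "p_value": round(r.p_value, 4),
            }
        )
    order = ["test", "direction", "exclusive", "carriers_high", "carriers_low",
             "n_high", "n_low", "n_variants", "p_value"]
    return pd.DataFrame(rows, columns=order)


def write_reproduction(outdir, sidedness: str = "two") -> RunManifest:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters={"sidedness": sidedness})
    manifest.inputs = {name: _sha256(fixture_path(f)) for name, f in FIXTURE_FILES.items()}
    report = reproduce_lipg(sidedness=sidedness)
    report.to_csv(outdir / "burden_report.tsv", sep="\t", index=False)
    (outdir / "burden_report.json").write_text(
        json.dumps(report.to_dict(orient="records"), indent=2) + "\n"
    )
    manifest.record("reproduce", "ok", rows=len(report))
    manifest.to_json(outdir / "manifest.json")
    return manifest


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Run catalog -> assay -> burden (-> ld, assoc when inputs present).

    ``config`` keys: variants, cohorts, carriers (paths, required);
    assay or calls (one required for directional tests); genotypes +
    ld_pair (optional); phenotypes + assoc (optional); alpha, sidedness.
    Any stage error aborts the run with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters={k: str(v) for k, v in config.items()})
    for key in ("variants", "cohorts", "carriers"):
        if key not in config:
            raise ConfigurationError(f"pipeline config missing required key {key!r}")
        manifest.inputs[key] = _sha256(Path(config[key]))

    stage = "catalog"
    try:
        cohorts = catalog.load_cohorts(config["cohorts"])
        records = catalog.load_catalog(config["variants"], cohorts)
        carriers = catalog.CarrierTable.load(config["carriers"])
        carriers.validate_against(records)
        manifest.record(stage, "ok", n_variants=len(records))

        stage = "assay"
        calls = None
        if "assay" in config:
            wells = assay.load_wells(config["assay"])
            calls = assay.call_variants(wells, alpha=float(config.get("alpha", 0.05)))
            assay.save_calls(calls, outdir / "functional_calls.tsv")
            manifest.record(stage, "ok", n_calls=len(calls))
        elif "calls" in config:
            calls = assay.load_calls(config["calls"])
            manifest.record(stage, "ok", n_calls=len(calls), source="precomputed")
        else:
            manifest.record(stage, "skipped")

        stage = "burden"
        sidedness = str(config.get("sidedness", "two"))
        results = [burden.cast(records, carriers, cohorts, sidedness=sidedness)]
        if calls is not None:
            for exclusive in (False, True):
                for direction in ("decrease", "increase"):
                    results.append(
                        burden.directional_cast(
                            records, carriers, calls, direction,
                            exclusive=exclusive, cohorts=cohorts, sidedness=sidedness,
                        )
                    )
        report = pd.DataFrame(
            [
                {
                    "test": r.test_name,
                    "direction": r.direction,
                    "exclusive": r.exclusive,
                    "carriers_high": r.table.a,
                    "carriers_low": r.table.c,
                    "p_value": r.p_value,
                }
                for r in results
            ]
        )
        report.to_csv(outdir / "burden_report.tsv", sep="\t", index=False, float_format="%.6g")
        manifest.record(stage, "ok", n_tests=len(results))

        stage = "ld"
        if "genotypes" in config and "ld_pair" in config:
            va, vb = config["ld_pair"]
            df = pd.read_csv(config["genotypes"], sep="\t")
            table = ld.table_from_long(df, va, vb)
            h, stats_ = ld.pair_ld(table)
            pd.DataFrame(
                [
                    {
                        "variant_a": va,
                        "variant_b": vb,
                        "D": stats_.D,
                        "D_prime": stats_.D_prime,
                        "r2": stats_.r2,
                        "n_individuals": table.n_individuals,
                    }
                ]
            ).to_csv(outdir / "ld_report.tsv", sep="\t", index=False, float_format="%.6g")
            manifest.record(stage, "ok", r2=stats_.r2)
        else:
            manifest.record(stage, "skipped")

        stage = "assoc"
        if "phenotypes" in config and "assoc_genotypes" in config:
            pheno = pd.read_csv(config["phenotypes"], sep="\t")
            geno = pd.read_csv(config["assoc_genotypes"], sep="\t")
            variant = config.get("assoc_variant")
            trait = config.get("assoc_trait", "trait")
            transform = config.get("assoc_transform", "identity")
            wide = geno.pivot_table(index="individual_id", columns="variant_id", values="genotype")
            merged = pheno.set_index("individual_id").join(wide[[variant]], how="inner").dropna()
            result = assoc.additive_regression(
                merged[variant], merged[trait], transform=transform, variant_id=variant
            )
            pd.DataFrame([result.__dict__]).to_csv(
                outdir / "assoc_report.tsv", sep="\t", index=False, float_format="%.6g"
            )
            manifest.record(stage, "ok", beta=result.beta)
        else:
            manifest.record(stage, "skipped")
    except Exception as exc:
        manifest.record(stage, "error", message=str(exc))
        manifest.to_json(outdir / "manifest.json")
        raise ConfigurationError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.to_json(outdir / "manifest.json")
    return manifest
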