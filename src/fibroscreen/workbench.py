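"""Pipeline orchestration, validated table I/O, configuration and CLI.

Ties the stages together: synthetic-data generation -> (optional) image
quantification -> plate QC + percent inhibition -> hit calling, and
expression simulation -> batch correction -> moderated DE -> signature
comparison.  Every run writes a manifest recording the config echo, seeds,
row counts and SHA-256 checksums of each output so reruns are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import hitcall, imquant, screenstats, signature, synthgen

log = logging.getLogger("fibroscreen")


class SchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


# column name -> required dtype kind ('f' float-like, 'i' integer, 's' string)
SCHEMAS: dict[str, dict[str, str]] = {
    "plate_map": dict(plate="s", well="s", donor="s", shrna_id="s", gene="s", role="s"),
    "well_table": dict(
        plate="s", well="s", donor="s", density="f", area="f", nuclei="i", score="f"
    ),
    "qc": dict(donor="s", z_prime="f", window="f", n_neg="i", n_pos="i", passed="s"),
    "inhibition": dict(shrna_id="s", gene="s", donor="s", pct_inhibition="f"),
    "hits": dict(
        gene="s", tier="s", n_gt_hi="i", n_in_lo_mid="i", n_in_lo_hi="i",
        best_mean="f", rank="i",
    ),
    "de_results": dict(
        probe="s", log2fc="f", t="f", p="f", q="f", lods="f", avg_expr="f",
        significant="s",
    ),
}

_KIND_CHECK = {
    "f": lambda s: pd.api.types.is_numeric_dtype(s),
    "i": lambda s: pd.api.types.is_integer_dtype(s),
    "s": lambda s: True,
}


def validate_table(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Check a table against a declared schema; extra columns warn, bad types raise."""
    schema = SCHEMAS[schema_name]
    for col, kind in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{schema_name}: missing column {col!r}")
        if not _KIND_CHECK[kind](df[col]):
            raise SchemaError(
                f"{schema_name}: column {col!r} has dtype {df[col].dtype}, "
                f"expected kind {kind!r}"
            )
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(
            f"{schema_name}: unknown columns {extra} preserved", stacklevel=2
        )
    return df


def read_table(path, schema_name: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return validate_table(df, schema_name)


def write_table(df: pd.DataFrame, path, schema_name: str | None = None) -> Path:
    if schema_name is not None:
        validate_table(df, schema_name)
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# pipeline config + runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; JSON/YAML round-trippable."""

    seed: int = 0
    mode: str = "all"  # screen-from-images | screen-from-tables | signature | all
    out_dir: str = "fibroscreen_out"
    screen: synthgen.ScreenConfig = field(default_factory=synthgen.ScreenConfig)
    study: synthgen.StudyConfig = field(default_factory=synthgen.StudyConfig)
    quant: imquant.QuantParams = field(default_factory=imquant.QuantParams)
    tiers: hitcall.TierRules = field(default_factory=hitcall.TierRules)
    gates: screenstats.QCGates = field(default_factory=screenstats.QCGates)
    thresholds: signature.DEThresholds = field(default_factory=signature.DEThresholds)
    exclude_samples: tuple[str, ...] = ()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        sub = {
            "screen": synthgen.ScreenConfig, "study": synthgen.StudyConfig,
            "quant": imquant.QuantParams, "tiers": hitcall.TierRules,
            "gates": screenstats.QCGates, "thresholds": signature.DEThresholds,
        }
        for key, typ in sub.items():
            if key in kw and isinstance(kw[key], dict):
                d = kw[key]
                if key == "screen":
                    if "shrna_panel" in d:
                        d["shrna_panel"] = tuple(
                            (str(g), int(k)) for g, k in d["shrna_panel"]
                        )
                    if "efficacy_model" in d and isinstance(d["efficacy_model"], dict):
                        d["efficacy_model"] = synthgen.EfficacyMixture(
                            **d["efficacy_model"]
                        )
                for tup in ("effect_range", "batch_scale_range",
                            "baseline_mean_range", "shape"):
                    if tup in d and isinstance(d[tup], list):
                        d[tup] = tuple(d[tup])
                kw[key] = typ(**d)
        if "exclude_samples" in kw:
            kw["exclude_samples"] = tuple(kw["exclude_samples"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return synthgen.config_to_json(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    The manifest maps each output file to its row count and SHA-256 checksum
    and echoes the full configuration and derived stage seeds, so a rerun
    with the same config can be verified byte-for-byte.
    """
    if config.mode not in ("screen-from-images", "screen-from-tables",
                           "signature", "all"):
        raise SchemaError(f"unknown mode {config.mode!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seeds": {},
        "outputs": {},
        "status": "incomplete",
    }

    def record(name: str, path: Path, n_rows: int | None) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "rows": n_rows, "sha256": _sha256(path),
        }

    try:
        if config.mode in ("screen-from-tables", "screen-from-images", "all"):
            seed = _derive_seed(config.seed, "screen")
            manifest["seeds"]["screen"] = seed
            screen_cfg = dataclasses.replace(config.screen, seed=seed)
            plate_map, well_table, truth = synthgen.simulate_screen(screen_cfg)
            log.info("simulated screen: %d wells, %d donors",
                     len(well_table), screen_cfg.n_donors)

            if config.mode == "screen-from-images":
                well_table = _requantify_from_images(
                    plate_map, well_table, truth, config, out
                )

            p = write_table(plate_map, out / "plate_map.csv", "plate_map")
            record("plate_map", p, len(plate_map))
            p = write_table(well_table, out / "well_table.csv", "well_table")
            record("well_table", p, len(well_table))
            truth.shrna_efficacy is not None and record(
                "shrna_truth",
                write_table(truth.shrna_efficacy, out / "shrna_truth.csv"),
                len(truth.shrna_efficacy),
            )

            qc = screenstats.qc_screen(plate_map, well_table, config.gates)
            qc_out = qc.assign(passed=qc["passed"].astype(str))
            p = write_table(qc_out, out / "qc.csv", "qc")
            record("qc", p, len(qc))

            if (plate_map["role"] == synthgen.ROLE_TEST).any():
                inhib = screenstats.inhibition_table(plate_map, well_table)
                p = write_table(inhib, out / "inhibition.csv", "inhibition")
                record("inhibition", p, len(inhib))
                hits = hitcall.call_hits(inhib, config.tiers)
                p = write_table(hits, out / "hits.csv", "hits")
                record("hits", p, len(hits))
                (out / "hits_summary.json").write_text(
                    json.dumps(
                        hits.groupby("tier")["gene"].apply(list).to_dict(),
                        indent=2, sort_keys=True,
                    )
                )
                record("hits_summary", out / "hits_summary.json", len(hits))

        if config.mode in ("signature", "all"):
            seed = _derive_seed(config.seed, "study")
            manifest["seeds"]["study"] = seed
            study_cfg = dataclasses.replace(config.study, seed=seed)
            matrix, meta, truth = synthgen.simulate_expression_study(study_cfg)
            comparison, de_base, de_p4 = signature_stage(
                matrix, meta, config.thresholds,
                exclude_samples=config.exclude_samples,
            )
            for name, de in (("de_baseline", de_base), ("de_p4", de_p4)):
                de_out = de.reset_index().assign(
                    significant=de["significant"].astype(str).to_numpy()
                )
                p = write_table(de_out, out / f"{name}.tsv", "de_results")
                record(name, p, len(de))
            (out / "signature_comparison.json").write_text(
                json.dumps(dataclasses.asdict(comparison), indent=2)
            )
            record("signature_comparison", out / "signature_comparison.json", 1)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.error("pipeline stage failed: %s", exc)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _requantify_from_images(plate_map, well_table, truth, config, out):
    """Render each well and replace table quantities with image-derived ones."""
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    spec = synthgen.ImageSpec()
    rng = np.random.default_rng(_derive_seed(config.seed, "images"))
    rows = []
    merged = well_table.merge(truth.well_truth, on=["plate", "well", "donor"])
    for _, row in merged.iterrows():
        n_nuc = min(int(row["true_nuclei"]) // 12, 24)  # scale to field capacity
        stack, _ = synthgen.render_well_image(
            n_nuc, float(row["true_mean_score"]), spec, rng
        )
        path = img_dir / f"{row['plate']}_{row['well']}.tiff"
        imquant.write_image(path, stack)
        wq = imquant.quantify_asma(stack, config.quant)
        if not wq.defined:
            log.warning("well %s/%s: no nuclei detected; excluded",
                        row["plate"], row["well"])
            continue
        rows.append(
            dict(
                plate=row["plate"], well=row["well"], donor=row["donor"],
                density=wq.density, area=float(wq.area), nuclei=wq.nuclei,
                score=wq.score,
            )
        )
    return pd.DataFrame(rows)


def signature_stage(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: signature.DEThresholds = signature.DEThresholds(),
    exclude_samples: tuple[str, ...] = (),
):
    """Batch-correct, run per-passage DE, and compare the two signatures.

    Replicate samples (those bridging the batches) are used for the batch
    correction and then dropped, together with any explicitly excluded
    samples, before differential expression — mirroring a design where
    technical replicates exist only to estimate the batch terms.
    """
    corrected, _ = signature.batch_correct(matrix, meta)
    keep = meta["replicate_of"].fillna("").eq("") if "replicate_of" in meta else pd.Series(True, index=meta.index)
    keep &= ~meta["sample_id"].isin(exclude_samples)
    meta_use = meta[keep].reset_index(drop=True)
    mat_use = corrected[meta_use["sample_id"].to_numpy()]

    de = {}
    for passage in ("P0P1", "P4"):
        sel = meta_use["passage"] == passage
        de[passage] = signature.moderated_de(
            mat_use[meta_use.loc[sel, "sample_id"].to_numpy()],
            meta_use[sel], thresholds=thresholds,
        )
    degs_base = signature.select_degs(de["P0P1"], thresholds)
    degs_p4 = signature.select_degs(de["P4"], thresholds)
    comparison = signature.compare_signatures(
        degs_base, degs_p4,
        lfc_base=de["P0P1"]["log2fc"], lfc_follow=de["P4"]["log2fc"],
    )
    return comparison, de["P0P1"], de["P4"]


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="INFO-level logging.")
def cli(verbose: bool) -> None:
    """Phenotypic RNAi-screen analysis toolkit."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _load_config(config_path, seed, out_dir, mode) -> PipelineConfig:
    cfg = PipelineConfig.from_file(config_path) if config_path else PipelineConfig()
    if seed is not None:
        cfg.seed = seed
    if out_dir is not None:
        cfg.out_dir = out_dir
    if mode is not None:
        cfg.mode = mode
    return cfg


_shared = [
    click.option("--config", "config_path", type=click.Path(exists=True),
                 default=None, help="JSON or YAML pipeline config."),
    click.option("--seed", type=int, default=None, help="Master seed override."),
    click.option("--out-dir", type=click.Path(), default=None),
]


def _with_shared(f):
    for opt in reversed(_shared):
        f = opt(f)
    return f


@cli.command()
@_with_shared
@click.option("--mode", type=click.Choice(
    ["screen-from-images", "screen-from-tables", "signature", "all"]),
    default="all")
def run(config_path, seed, out_dir, mode):
    """Run the configured pipeline stages end to end."""
    cfg = _load_config(config_path, seed, out_dir, mode)
    manifest = run_pipeline(cfg)
    click.echo(json.dumps({k: manifest[k] for k in ("status", "seeds")}, indent=2))


@cli.command()
@_with_shared
def simulate(config_path, seed, out_dir):
    """Generate synthetic screen tables only."""
    cfg = _load_config(config_path, seed, out_dir, "screen-from-tables")
    run_pipeline(cfg)
    click.echo(f"wrote screen tables to {cfg.out_dir}")


@cli.command()
@click.argument("image", type=click.Path(exists=True))
def quantify(image):
    """Quantify one two-channel TIFF into D, A, N and the D*A/N score."""
    stack = imquant.read_image(image)
    wq = imquant.quantify_asma(stack)
    click.echo(json.dumps(dataclasses.asdict(wq), indent=2))


@cli.command()
@click.argument("plate_map_csv", type=click.Path(exists=True))
@click.argument("well_table_csv", type=click.Path(exists=True))
@click.option("--out", "out_csv", type=click.Path(), default="qc.csv")
def qc(plate_map_csv, well_table_csv, out_csv):
    """Plate QC (Z', assay window) from plate map + well table CSVs."""
    pm = read_table(plate_map_csv, "plate_map")
    wt = read_table(well_table_csv, "well_table")
    rep = screenstats.qc_screen(pm, wt)
    write_table(rep.assign(passed=rep["passed"].astype(str)), out_csv, "qc")
    click.echo(rep.to_string(index=False))


@cli.command()
@click.argument("inhibition_csv", type=click.Path(exists=True))
@click.option("--out", "out_csv", type=click.Path(), default="hits.csv")
def hits(inhibition_csv, out_csv):
    """Tiered hit calls from a per-(shRNA, donor) inhibition CSV."""
    inhib = read_table(inhibition_csv, "inhibition")
    table = hitcall.call_hits(inhib)
    write_table(table, out_csv, "hits")
    click.echo(table.to_string(index=False))


@cli.command(name="signature")
@_with_shared
def signature_cmd(config_path, seed, out_dir):
    """Run the expression-signature stage on simulated data."""
    cfg = _load_config(config_path, seed, out_dir, "signature")
    run_pipeline(cfg)
    click.echo(f"wrote signature outputs to {cfg.out_dir}")


if __name__ == "__main__":  # pragma: no cover
    cli()
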