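"""End-to-end orchestration and the `groovedock` command-line interface.

Subcommands: simulate-structures, simulate-images, simulate-bifc, dock,
interface, coloc, bifc, align, stats.  Every run writes a manifest (resolved
configuration + seed + package version) sufficient to reproduce it.

Exit codes: 0 success, 2 configuration error, 3 data error, 4 groove
occluded.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, bifc, coloc, groupstats, seqstats, synthetic_data
from .docking import ClashParams, GrooveOccludedError, template_guided_dock
from .interface import SasaParams, buried_area, contact_pairs, groove_lining
from .structio import (
    HelixSegment,
    StructureError,
    load_fragment_table,
    read_pdb,
    write_pdb,
)

logger = logging.getLogger("groovedock")

EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_OCCLUDED = 4


def _manifest(outdir: Path, command: str, config: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"command": command, "version": __version__, "config": config}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def parse_segment(text: str, label: str = "") -> HelixSegment:
    """Parse 'CHAIN:start-end' into a HelixSegment."""
    try:
        chain, rng = text.split(":")
        start, end = rng.split("-")
        return HelixSegment(chain, int(start), int(end), label=label or text)
    except (ValueError, TypeError) as exc:
        raise click.UsageError(f"bad segment {text!r}; expected CHAIN:start-end") from exc


# ---------------------------------------------------------------------------
# Library-level runners
# ---------------------------------------------------------------------------

def run_dock_and_score(cfg: dict) -> dict:
    """Template-guided dock plus interface scoring; writes artifacts.

    cfg keys: template, query, receptor (PDB paths), filler, target_m4
    (CHAIN:start-end), step, clash_cutoff, occlusion_ceiling, probe_radius,
    n_sphere_points, helices (optional fragment-table path for groove-lining
    labels), outdir.
    """
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    template = read_pdb(cfg["template"])
    query = read_pdb(cfg["query"])
    receptor = read_pdb(cfg["receptor"])
    filler = parse_segment(cfg["filler"], "filler")
    target = parse_segment(cfg["target_m4"], "target-m4")
    params = ClashParams(cutoff=float(cfg.get("clash_cutoff", 2.5)))
    result = template_guided_dock(
        template=template,
        filler=filler,
        query=query,
        receptor=receptor,
        target_m4=target,
        step=float(cfg.get("step", 1.0)),
        p=params,
        occlusion_ceiling=int(cfg.get("occlusion_ceiling", 25)),
    )
    docked = result.transform.apply_structure(query)
    sasa_params = SasaParams(
        probe_radius=float(cfg.get("probe_radius", 1.4)),
        n_sphere_points=int(cfg.get("n_sphere_points", 960)),
    )
    iface = buried_area(docked, receptor, sasa_params)
    iface.contacts = contact_pairs(docked, receptor)
    if cfg.get("helices"):
        helices = list(load_fragment_table(cfg["helices"]).values())
        iface.groove_lining = groove_lining(query, helices, result.transform.inverse().apply_structure(receptor))
    result.buried_area = iface.buried_area

    write_pdb(docked, outdir / "docked_query.pdb")
    payload = result.as_dict()
    payload["interface"] = iface.as_dict()
    (outdir / "result.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    _manifest(outdir, "dock", cfg)
    return payload


def run_coloc_batch(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-cell thresholded PCC + group summary + cumulative-frequency table.

    cfg keys: manifest (TSV: cell_id, group, path), outdir, both_above,
    regression.  Unreadable cells are skipped with a warning; an empty group
    fails the run.
    """
    import tifffile

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(cfg["manifest"], sep="\t")
    rows = []
    for _, entry in manifest.iterrows():
        try:
            stack = tifffile.imread(entry["path"])
            img = coloc.TwoChannelImage(ch1=stack[0], ch2=stack[1])
            res = coloc.thresholded_pcc(
                img,
                both_above=bool(cfg.get("both_above", False)),
                regression=cfg.get("regression", "ols"),
            )
        except (OSError, ValueError, IndexError) as exc:
            logger.warning("skipping cell %s: %s", entry["cell_id"], exc)
            continue
        rows.append(
            {
                "cell_id": entry["cell_id"],
                "group": entry["group"],
                "t1": res.t1,
                "t2": res.t2,
                "pcc": res.pcc,
                "n_pixels": res.n_pixels_used,
            }
        )
    per_cell = pd.DataFrame(rows)
    for group in manifest["group"].unique():
        if per_cell.empty or group not in set(per_cell["group"]):
            raise StructureError(f"group {group!r} has no readable cells")
    groups = {g: per_cell.loc[per_cell["group"] == g, "pcc"].tolist()
              for g in per_cell["group"].unique()}
    summary, test = coloc.summarize_groups(groups)

    cdf_rows = []
    for g, values in groups.items():
        ordered = np.sort(values)
        for i, v in enumerate(ordered, start=1):
            cdf_rows.append({"group": g, "pcc": v, "cum_freq": i / len(ordered)})
    cdf = pd.DataFrame(cdf_rows)

    per_cell.to_csv(outdir / "per_cell.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    cdf.to_csv(outdir / "cumulative_frequency.tsv", sep="\t", index=False)
    if test is not None:
        (outdir / "test.json").write_text(json.dumps(test.as_dict(), indent=1))
    _manifest(outdir, "coloc", cfg)
    return per_cell, summary, cdf


def run_bifc_batch(cfg: dict) -> bifc.BiFCResult:
    """BiFC gating + normalization + Welch ANOVA from a TSV of records.

    cfg keys: table (TSV: cell_id, group, background, cy3, venus), control,
    factor, outdir.
    """
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(cfg["table"], sep="\t")
    result = bifc.bifc_pipeline(
        records, control_group=cfg["control"], factor=float(cfg.get("factor", 3.5))
    )
    result.per_cell.to_csv(outdir / "per_cell.tsv", sep="\t", index=False)
    (outdir / "result.json").write_text(json.dumps(result.as_dict(), indent=1))
    _manifest(outdir, "bifc", cfg)
    return result


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging")
def cli(verbose: bool) -> None:
    """Groove docking, interface scoring and cell-assay statistics."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("simulate-structures")
@click.option("--outdir", type=click.Path(path_type=Path), required=True)
@click.option("--angle", type=float, default=0.0, show_default=True,
              help="planted rotation about the target M4 axis (degrees)")
@click.option("--seed", type=int, default=0, show_default=True)
def cmd_simulate_structures(outdir: Path, angle: float, seed: int) -> None:
    """Write long/short bundles, receptor, and a planted docked scene."""
    pair = synthetic_data.make_long_short_pair()
    receptor = synthetic_data.make_receptor_fixture()
    scene = synthetic_data.plant_complex(pair, receptor, true_angle=angle, seed=seed)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pdb(pair.long.structure, outdir / "long.pdb")
    write_pdb(pair.short.structure, outdir / "short.pdb")
    write_pdb(receptor.structure, outdir / "receptor.pdb")
    write_pdb(scene.bundle, outdir / "scene_bundle.pdb")
    write_pdb(scene.receptor, outdir / "scene_receptor.pdb")
    helix_rows = [
        f"{seg.label}\t{seg.chain_id}\t{seg.start}\t{seg.end}"
        for seg in pair.short.helices
    ]
    (outdir / "short_helices.tsv").write_text(
        "# label\tchain\tstart\tend\n" + "\n".join(helix_rows) + "\n"
    )
    truth = {
        "true_angle": scene.true_angle,
        "rotation": scene.ground_truth.rotation.tolist(),
        "translation": scene.ground_truth.translation.tolist(),
        "filler": [pair.filler.chain_id, pair.filler.start, pair.filler.end],
        "target_m4": [
            receptor.m4_segments[0].chain_id,
            receptor.m4_segments[0].start,
            receptor.m4_segments[0].end,
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    _manifest(outdir, "simulate-structures", {"angle": angle, "seed": seed})
    click.echo(f"wrote fixtures to {outdir}")


@cli.command("simulate-images")
@click.option("--outdir", type=click.Path(path_type=Path), required=True)
@click.option("--rho", type=float, default=0.5, show_default=True)
@click.option("--cells", type=int, default=30, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--group", default="sim", show_default=True)
def cmd_simulate_images(outdir: Path, rho: float, cells: int, seed: int, group: str) -> None:
    """Write two-channel TIFF cells with known co-localized fraction."""
    params = synthetic_data.ColocSimParams(n_cells=cells, coloc_fraction=rho, seed=seed)
    simulated = synthetic_data.simulate_coloc_images(params)
    manifest = synthetic_data.write_coloc_batch(simulated, outdir, group=group)
    click.echo(f"wrote {cells} cells; manifest {manifest}")


@cli.command("simulate-bifc")
@click.option("--out", type=click.Path(path_type=Path), required=True)
@click.option("--group", "groups", multiple=True, required=True,
              help="NAME:reporter_fold:n_cells, repeatable")
@click.option("--background", type=float, default=100.0, show_default=True)
@click.option("--cv", type=float, default=0.1, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
def cmd_simulate_bifc(out: Path, groups, background: float, cv: float, seed: int) -> None:
    """Write a BiFC intensity table for one or more simulated groups."""
    tables = []
    for i, spec in enumerate(groups):
        try:
            name, fold, n = spec.split(":")
        except ValueError:
            raise click.UsageError(f"bad group {spec!r}; expected NAME:fold:n")
        params = synthetic_data.BiFCSimParams(
            n_cells=int(n), background_mean=background,
            reporter_fold=float(fold), noise_cv=cv, seed=seed + i,
        )
        tables.append(synthetic_data.simulate_bifc(params, group=name))
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(tables, ignore_index=True).to_csv(out, sep="\t", index=False)
    click.echo(f"wrote {out}")


@cli.command("dock")
@click.option("--template", required=True, type=click.Path(exists=True))
@click.option("--query", required=True, type=click.Path(exists=True))
@click.option("--receptor", required=True, type=click.Path(exists=True))
@click.option("--filler", required=True, help="CHAIN:start-end in the template")
@click.option("--target-m4", required=True, help="CHAIN:start-end in the receptor")
@click.option("--step", type=float, default=1.0, show_default=True)
@click.option("--clash-cutoff", type=float, default=2.5, show_default=True)
@click.option("--ceiling", type=int, default=25, show_default=True)
@click.option("--helices", type=click.Path(exists=True), default=None,
              help="fragment table for groove-lining labels")
@click.option("--outdir", type=click.Path(path_type=Path), required=True)
def cmd_dock(template, query, receptor, filler, target_m4, step, clash_cutoff,
             ceiling, helices, outdir: Path) -> None:
    """Template-guided dock plus buried-area scoring."""
    cfg = {
        "template": template, "query": query, "receptor": receptor,
        "filler": filler, "target_m4": target_m4, "step": step,
        "clash_cutoff": clash_cutoff, "occlusion_ceiling": ceiling,
        "helices": helices, "outdir": str(outdir),
    }
    payload = run_dock_and_score(cfg)
    click.echo(
        f"best angle {payload['best_angle']} deg, clash count "
        f"{payload['clash_count']}, buried area {payload['buried_area']:.0f} A^2"
    )


@cli.command("interface")
@click.option("--a", "path_a", required=True, type=click.Path(exists=True))
@click.option("--b", "path_b", required=True, type=click.Path(exists=True))
@click.option("--probe", type=float, default=1.4, show_default=True)
@click.option("--points", type=int, default=960, show_default=True)
@click.option("--helices", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def cmd_interface(path_a, path_b, probe, points, helices, out: Path) -> None:
    """Buried surface area + contacts between two structures."""
    a = read_pdb(path_a)
    b = read_pdb(path_b)
    params = SasaParams(probe_radius=probe, n_sphere_points=points)
    result = buried_area(a, b, params)
    result.contacts = contact_pairs(a, b)
    if helices:
        result.groove_lining = groove_lining(
            a, list(load_fragment_table(helices).values()), b
        )
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(result.as_dict(), indent=1))
    click.echo(f"buried area {result.buried_area:.1f} A^2 ({len(result.contacts)} contacts)")


@cli.command("coloc")
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--outdir", type=click.Path(path_type=Path), required=True)
@click.option("--both-above", is_flag=True)
@click.option("--regression", type=click.Choice(["ols", "tls"]), default="ols",
              show_default=True)
def cmd_coloc(manifest, outdir: Path, both_above: bool, regression: str) -> None:
    """Batch thresholded-PCC over a manifest of two-page TIFF cells."""
    per_cell, summary, _ = run_coloc_batch(
        {"manifest": manifest, "outdir": str(outdir),
         "both_above": both_above, "regression": regression}
    )
    click.echo(summary.to_string(index=False))


@cli.command("bifc")
@click.option("--in", "table", required=True, type=click.Path(exists=True))
@click.option("--control", required=True)
@click.option("--factor", type=float, default=3.5, show_default=True)
@click.option("--outdir", type=click.Path(path_type=Path), required=True)
def cmd_bifc(table, control, factor, outdir: Path) -> None:
    """Classify / normalize a BiFC table and run Welch's ANOVA."""
    result = run_bifc_batch(
        {"table": table, "control": control, "factor": factor, "outdir": str(outdir)}
    )
    click.echo(result.per_group.to_string(index=False))
    click.echo(f"Welch F={result.test.statistic:.3f} p={result.test.p:.3g}")


@cli.command("align")
@click.option("--a", "path_a", required=True, type=click.Path(exists=True))
@click.option("--b", "path_b", required=True, type=click.Path(exists=True))
@click.option("--matrix", default="BLOSUM62", show_default=True)
@click.option("--gap-open", type=float, default=12.0, show_default=True)
@click.option("--gap-extend", type=float, default=2.0, show_default=True)
@click.option("--out", type=click.Path(path_type=Path), default=None)
def cmd_align(path_a, path_b, matrix, gap_open, gap_extend, out) -> None:
    """Global alignment of the first records of two FASTA files."""
    from Bio import SeqIO

    rec_a = next(SeqIO.parse(path_a, "fasta"))
    rec_b = next(SeqIO.parse(path_b, "fasta"))
    result = seqstats.global_align(
        str(rec_a.seq), str(rec_b.seq),
        matrix=seqstats.load_matrix(matrix),
        gap_open=gap_open, gap_extend=gap_extend,
    )
    click.echo(str(result))
    if out:
        Path(out).write_text(json.dumps(result.as_dict(), indent=1))


@cli.command("stats")
@click.option("--in", "table", required=True, type=click.Path(exists=True))
@click.option("--test", "which", required=True,
              type=click.Choice(["kw", "dunn", "welch"]))
@click.option("--group-col", default="group", show_default=True)
@click.option("--value-col", default="value", show_default=True)
@click.option("--adjust", type=click.Choice(["none", "bonferroni", "holm"]),
              default="bonferroni", show_default=True)
@click.option("--out", type=click.Path(path_type=Path), required=True)
def cmd_stats(table, which, group_col, value_col, adjust, out: Path) -> None:
    """Run a group test on a TSV of (group, value) rows."""
    df = pd.read_csv(table, sep="\t")
    for col in (group_col, value_col):
        if col not in df.columns:
            raise click.UsageError(f"column {col!r} not in {table}")
    labels = list(df[group_col].unique())
    groups = [df.loc[df[group_col] == g, value_col].to_numpy() for g in labels]
    if which == "kw":
        payload = groupstats.kruskal_wallis(groups).as_dict()
    elif which == "welch":
        payload = groupstats.welch_anova(groups).as_dict()
    else:
        payload = {
            "method": "dunn",
            "adjust": adjust,
            "pairwise": groupstats.dunn_posthoc(groups, adjust=adjust, labels=labels)
            .to_dict(orient="records"),
        }
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(payload, indent=1))
    click.echo(json.dumps(payload, indent=1))


def main() -> None:
    """Console entry point with the documented exit-code mapping."""
    try:
        cli.main(standalone_mode=False)
    except click.UsageError as exc:
        click.echo(f"error: {exc.format_message()}", err=True)
        sys.exit(EXIT_CONFIG)
    except click.ClickException as exc:
        exc.show()
        sys.exit(EXIT_CONFIG)
    except click.exceptions.Abort:
        sys.exit(EXIT_CONFIG)
    except GrooveOccludedError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(EXIT_OCCLUDED)
    except (StructureError, OSError, ValueError, KeyError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(EXIT_DATA)


if __name__ == "__main__":
    main()
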