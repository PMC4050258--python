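"""Human-readable run summary mirroring the figure logic of the analysis:
pair-correlation clusters, dosage-group t-test, boundary-call counts by end
and direction, and the signed association matrix. When the run carries a
synthetic truth sidecar, per-stage recovery metrics are appended.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _table(df: pd.DataFrame, title: str) -> str:
    if df is None or not len(df):
        return f"== {title} ==\n(empty)\n"
    return f"== {title} ==\n{df.to_string(index=False)}\n"


def _read(run_dir: Path, name: str) -> pd.DataFrame | None:
    p = run_dir / name
    if not p.exists():
        return None
    try:
        return pd.read_csv(p, sep="\t")
    except Exception:
        return None


def render_report(run_dir: str | Path) -> str:
    """Assemble the text report from whatever stage outputs are present;
    missing stages produce warnings, not errors."""
    run_dir = Path(run_dir)
    parts = ["stressweave run report", "=" * 24, ""]
    warnings = []

    cors = _read(run_dir, "pair_correlations.tsv")
    if cors is not None and len(cors):
        cluster = (cors.groupby(["cluster_id"])
                   .agg(n_pairs=("rho", "size"), median_rho=("rho", "median"))
                   .reset_index())
        parts.append(_table(cluster, "pair-profile correlation clusters"))
        geo = (cors.groupby("geometry")
               .agg(n=("rho", "size"), median_rho=("rho", "median")).reset_index())
        parts.append(_table(geo, "pair correlation by geometry"))
    else:
        warnings.append("pair correlations missing")

    ttest_path = run_dir / "dosage_ttest.json"
    if ttest_path.exists():
        t = json.loads(ttest_path.read_text())
        parts.append("== antisense dosage vs protein change (Welch t-test) ==")
        for k in sorted(t):
            parts.append(f"  {k}: {t[k]}")
        parts.append("")
    else:
        warnings.append("dosage t-test missing")

    calls = _read(run_dir, "boundary_calls.tsv")
    if calls is not None:
        if len(calls) and calls["significant"].any():
            sig = calls[calls["significant"].astype(bool)]
            summary = (sig.groupby(["end", "direction"])["gene"].nunique()
                       .rename("n_genes").reset_index())
            parts.append(_table(summary, "significant boundary changes"))
        else:
            parts.append("== significant boundary changes ==\nzero significant boundaries\n")
    else:
        warnings.append("boundary calls missing")

    for mat_file in sorted(run_dir.glob("association_*.tsv")):
        if "tests" in mat_file.name or "changes" in mat_file.name:
            continue
        mat = pd.read_csv(mat_file, sep="\t", index_col=0)
        n_pos = int((mat.to_numpy() == 1).sum())
        n_neg = int((mat.to_numpy() == -1).sum())
        parts.append(
            f"== association matrix {mat_file.stem} ==\n"
            f"  families x ncRNAs: {mat.shape[0]} x {mat.shape[1]}; "
            f"positive cells: {n_pos}; negative cells: {n_neg}\n"
        )

    truth_path = run_dir / "truth.json"
    if truth_path.exists():
        parts.append(_recovery_section(run_dir, json.loads(truth_path.read_text())))

    if warnings:
        parts.append("warnings: " + "; ".join(warnings))
    return "\n".join(parts) + "\n"


def _recovery_section(run_dir: Path, truth: dict) -> str:
    lines = ["== recovery vs planted truth =="]
    calls = _read(run_dir, "boundary_calls.tsv")
    if calls is not None and truth.get("extensions"):
        planted = {(e["gene"], e["end"], e["timepoint"]) for e in truth["extensions"]}
        planted_genes = {g for g, _, _ in planted}
        sig = calls[calls["significant"].astype(bool)] if len(calls) else calls
        hit = {(r["gene"], r["end"], r["timepoint"]) for _, r in sig.iterrows()} if len(sig) else set()
        tp = len(planted & hit)
        fp = len({(g, e, t) for g, e, t in hit if g not in planted_genes})
        lines.append(f"  boundary extensions: {tp}/{len(planted)} recovered, "
                     f"{fp} false calls on unplanted genes")
    ptable = _read(run_dir, "pairs.tsv")
    if ptable is not None and truth.get("pairs"):
        truth_pairs = {(p["gene_a"], p["gene_b"]): p["geometry"] for p in truth["pairs"]}
        found = {(r["gene_a"], r["gene_b"]): r["geometry"] for _, r in ptable.iterrows()}
        ok = sum(1 for k, g in truth_pairs.items() if found.get(k) == g)
        lines.append(f"  pair geometries: {ok}/{len(truth_pairs)} recovered")
    for mat_file in sorted(run_dir.glob("association_*.tsv")):
        if "tests" in mat_file.name or "changes" in mat_file.name:
            continue
        if truth.get("modules"):
            mat = pd.read_csv(mat_file, sep="\t", index_col=0)
            got = sum(
                1 for m in truth["modules"]
                if m["family"] in mat.index and m["ncrna"] in mat.columns
                and mat.loc[m["family"], m["ncrna"]] != 0
            )
            lines.append(f"  planted modules in {mat_file.stem}: "
                         f"{got}/{len(truth['modules'])} significant")
    return "\n".join(lines) + "\n"
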