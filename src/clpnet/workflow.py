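"""End-to-end study workflow: configuration, orchestration, reporting.

A run is fully described by a :class:`RunConfig` (YAML or JSON): where the
panel comes from (a CSV or the synthetic generator), imputation and fit
settings, robustness scale, and which dyad-type networks to compare. Every
source of randomness is a named seed in the config, so a config determines
every emitted number; artifacts are plain CSV/JSON plus a Markdown report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .centrality import compute_centrality, standardize_centrality
from .comparison import compare_networks, top_bridging_edges
from .estimation import CLPNetwork, FitConfig, fit_clpn
from .impute import ImputationConfig, impute_covariates
from .panel import (
    DYAD_TYPES,
    DyadPanel,
    apply_exclusions,
    apply_reverse_scoring,
    describe,
    read_panel,
    write_panel,
)
from .robustness import bootstrap_edges, cs_coefficient, difference_tests
from .simulate import SyntheticSpec, default_study_spec, generate_dyads

log = logging.getLogger("clpnet")

DYAD_KEYS = [f"{g}-{r}" for g, r in DYAD_TYPES]
ALL_PAIRS = [
    (DYAD_KEYS[i], DYAD_KEYS[j])
    for i in range(len(DYAD_KEYS))
    for j in range(i + 1, len(DYAD_KEYS))
]


class WorkflowError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    simulate: dict | None = field(
        default_factory=lambda: {"seed": 0, "spec": None}
    )  # None when reading a CSV
    input: dict | None = None  # {'path': ..., 'column_map': optional path}
    already_scored: bool = False
    imputation: dict = field(default_factory=lambda: {"n_trees": 100, "seed": 1})
    fit: dict = field(default_factory=lambda: {"fold_seed": 2})
    robustness: dict = field(
        default_factory=lambda: {
            "run": True,
            "n_boot": 1000,
            "boot_seed": 3,
            "cs_reps_per_drop": 50,
            "cs_seed": 4,
            "indices": ["oei", "iei", "bei"],
        }
    )
    comparisons: list = field(default_factory=lambda: list(ALL_PAIRS))
    output_dir: str = "clpn_out"

    def to_dict(self) -> dict:
        return {
            "simulate": self.simulate,
            "input": self.input,
            "already_scored": self.already_scored,
            "imputation": self.imputation,
            "fit": self.fit,
            "robustness": self.robustness,
            "comparisons": [list(p) for p in self.comparisons],
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        cfg.comparisons = [tuple(p) for p in cfg.comparisons]
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True))


def load_or_simulate(config: RunConfig, outdir: Path) -> DyadPanel:
    if config.input:
        panel = read_panel(
            config.input["path"],
            column_map=config.input.get("column_map"),
            scored=config.already_scored,
        )
        log.info("read %d dyads from %s", len(panel), config.input["path"])
        return panel
    sim = config.simulate or {}
    if sim.get("spec"):
        spec = SyntheticSpec.from_json(sim["spec"])
        if "seed" in sim:
            spec.seed = int(sim["seed"])
    else:
        spec = default_study_spec(seed=int(sim.get("seed", 0)))
    panel, report, _ = generate_dyads(spec)
    write_panel(panel, outdir / "panel_raw.csv")
    _dump_json(report.to_dict(), outdir / "generation_report.json")
    log.info("simulated %d dyads (seed=%s)", len(panel), spec.seed)
    return panel


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the complete workflow; returns a manifest of artifacts."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = load_or_simulate(config, outdir)
    if not panel.scored:
        panel = apply_reverse_scoring(panel)
    panel, excl = apply_exclusions(panel)
    _dump_json(excl.to_dict(), outdir / "exclusion_log.json")

    desc = describe(panel)
    desc.to_csv(outdir / "descriptives.csv")
    _dump_json(
        {"cronbach_alpha": {w: desc.alpha[w] for w in desc.alpha}},
        outdir / "scale_reliability.json",
    )

    panel, imp_report = impute_covariates(
        panel, ImputationConfig(**config.imputation)
    )
    _dump_json(imp_report.to_dict(), outdir / "imputation_report.json")
    write_panel(panel, outdir / "panel_analysis.csv")

    from .panel import split_by_dyad_type

    parts = split_by_dyad_type(panel)
    fit_cfg = FitConfig(**config.fit)
    networks: dict[str, CLPNetwork] = {}
    for (g, r), sub in parts.items():
        key = f"{g}-{r}"
        if len(sub) < fit_cfg.n_folds:
            log.warning("skipping %s: only %d dyads", key, len(sub))
            continue
        net = fit_clpn(sub, fit_cfg)
        networks[key] = net
        net.save(outdir / f"net_{key}")
        cent = standardize_centrality(compute_centrality(net))
        cent.to_csv(outdir / f"centrality_{key}.csv")
        top_bridging_edges(net).to_csv(outdir / f"bridging_{key}.csv")
        log.info("fitted %s network (n=%d)", key, net.n_used)

    rob = dict(config.robustness)
    if rob.get("run", True):
        for key, net in networks.items():
            g, r = key.split("-")
            sub = parts[(g, r)]
            boot = bootstrap_edges(
                sub,
                fit_cfg,
                n_boot=int(rob.get("n_boot", 1000)),
                seed=int(rob.get("boot_seed", 0)),
            )
            boot.save(outdir / f"boot_{key}")
            diff = difference_tests(boot)
            diff.save(outdir / f"diff_{key}")
            cs_summary = {}
            for index in rob.get("indices", ["oei", "iei", "bei"]):
                cs = cs_coefficient(
                    sub,
                    fit_cfg,
                    index=index,
                    reps_per_drop=int(rob.get("cs_reps_per_drop", 50)),
                    seed=int(rob.get("cs_seed", 0)),
                )
                cs_summary[index] = cs.to_dict()
                cs.quantile_table().to_csv(
                    outdir / f"cs_{key}_{index}.csv", index=False,
                    float_format="%.10g",
                )
            _dump_json(cs_summary, outdir / f"cs_{key}.json")
            log.info("robustness done for %s", key)

    for a, b in config.comparisons:
        if a in networks and b in networks:
            res = compare_networks(networks[a], networks[b])
            _dump_json(res.to_dict(), outdir / f"compare_{a}_vs_{b}.json")

    _dump_json(
        {
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "package_version": __version__,
        },
        outdir / "provenance.json",
    )
    render_report(outdir)
    return {"output_dir": str(outdir), "networks": sorted(networks)}


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(outdir: str | Path) -> Path:
    """Assemble ``report.md`` from the artifact files in ``outdir``.

    Idempotent; raises :class:`WorkflowError` listing the stage to run if a
    required artifact is missing.
    """
    import pandas as pd

    outdir = Path(outdir)
    required = {
        "exclusion_log.json": "run-all (exclusions)",
        "descriptives.csv": "describe",
        "provenance.json": "run-all",
    }
    missing = [f"{f} (run: {stage})" for f, stage in required.items()
               if not (outdir / f).exists()]
    if missing:
        raise WorkflowError("missing artifacts: " + "; ".join(missing))

    prov = json.loads((outdir / "provenance.json").read_text())
    excl = json.loads((outdir / "exclusion_log.json").read_text())
    lines = [
        "# Cross-lagged panel network analysis report",
        "",
        f"Package version {prov['package_version']}, config hash "
        f"`{prov['config_hash']}`.",
        "",
        "## Sample",
        "",
        f"- dyads before exclusions: {excl['input_size']}",
        f"- removed for missing symptom responses: {excl['missing_symptoms']}",
        f"- removed for non-cohabitation: {excl['not_cohabiting']}",
        f"- analyzed: {excl['retained']}",
        "",
    ]
    rel_path = outdir / "scale_reliability.json"
    if rel_path.exists():
        rel = json.loads(rel_path.read_text())["cronbach_alpha"]
        lines += [
            "Scale internal consistency (Cronbach's alpha): "
            + ", ".join(f"{w}: {a:.2f}" for w, a in sorted(rel.items())),
            "",
        ]

    lines += ["## Descriptive statistics", ""]
    desc = pd.read_csv(outdir / "descriptives.csv")
    lines += [_md_table(desc.round(2)), ""]

    for key in DYAD_KEYS:
        cent_path = outdir / f"centrality_{key}.csv"
        if not cent_path.exists():
            continue
        lines += [f"## {key} network", ""]
        cent = pd.read_csv(cent_path)
        lines += ["Centrality (raw and standardized):", "",
                  _md_table(cent.round(3)), ""]
        bridging = outdir / f"bridging_{key}.csv"
        if bridging.exists():
            top = pd.read_csv(bridging)
            lines += ["Strongest bridging edges:", "", _md_table(top.round(3)), ""]
        cs_path = outdir / f"cs_{key}.json"
        if cs_path.exists():
            cs = json.loads(cs_path.read_text())
            lines += [
                "Centrality stability (CS coefficients): "
                + ", ".join(
                    f"{idx.upper()}: {d['cs']:.2f} ({d['verdict']})"
                    for idx, d in sorted(cs.items())
                ),
                "",
            ]

    comps = sorted(outdir.glob("compare_*_vs_*.json"))
    if comps:
        lines += ["## Network comparisons", ""]
        for path in comps:
            d = json.loads(path.read_text())
            name = path.stem.removeprefix("compare_").replace("_vs_", " vs ")
            cc = d["centrality_corr"]
            lines += [
                f"### {name}",
                "",
                f"- edge-matrix correlation r = {d['edge_corr']:.3f} "
                f"(p = {d['edge_corr_p']:.3f})",
                f"- edges with the same direction: "
                f"{100 * d['prop_same_direction']:.1f}% "
                f"({d['n_same']}/{d['n_edges']})",
                f"- centrality correlations: "
                + ", ".join(
                    f"{i.upper()} r = {cc[i]['r']:.2f} (p = {cc[i]['p']:.3f})"
                    for i in ("oei", "iei", "bei")
                ),
                "",
            ]

    out = outdir / "report.md"
    out.write_text("\n".join(lines))
    return out


def _md_table(df) -> str:
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(map(str, r)) + " |" for r in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


def plot_network(net: CLPNetwork, path: str | Path) -> None:
    """Basic circle-layout plot: nodes colored by community, arrows scaled by
    |weight|. No layout fidelity is promised; exports exist for real graphing
    tools."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(net.nodes)
    theta = 2 * np.pi * np.arange(n) / n
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    fig, ax = plt.subplots(figsize=(7, 7))
    wmax = np.abs(net.B_hat).max() or 1.0
    for i in range(n):
        for j in range(n):
            w = net.B_hat[i, j]
            if i == j or w == 0:
                continue
            ax.annotate(
                "",
                xy=xy[j],
                xytext=xy[i],
                arrowprops=dict(
                    arrowstyle="-|>",
                    color="tab:blue" if w > 0 else "tab:red",
                    alpha=min(1.0, 0.15 + abs(w) / wmax),
                    lw=2.5 * abs(w) / wmax,
                ),
            )
    colors = ["tab:orange" if nd.community == "child" else "tab:green"
              for nd in net.nodes]
    ax.scatter(xy[:, 0], xy[:, 1], s=700, c=colors, zorder=3)
    for k, nd in enumerate(net.nodes):
        ax.annotate(str(nd), xy[k], ha="center", va="center", fontsize=7, zorder=4)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
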