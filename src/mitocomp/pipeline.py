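"""Orchestration of the full two-genome comparison into a report bundle.

Stages: composition -> codon usage (RSCU, start/stop, degeneracy) ->
pairwise Ka/Ks against reference genomes -> gene-order comparison.
Outputs are deterministic TSV/JSON files; timestamps are confined to the
run log.  A stage failure is logged with the stage name and downstream
stages that can proceed do.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import codon_usage as cu
from . import composition as comp
from . import gene_order as go
from .alignment import AlignmentScoring
from .codes import genetic_code
from .genomes import AnnotatedGenome, extract_cds, gene_order_of, read_genbank
from .selection import pairwise_kaks_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run (flat key=value file format).

    Keys: query (repeatable path), reference (repeatable path),
    code_table {1,5}, rscu_partition {table8-standard, table5-mito},
    kaks_method {NG86, YN00}, gap_open, gap_extend, min_cluster_len,
    max_tdrl_block, outdir, seed.
    """

    queries: tuple[str, ...]
    references: tuple[str, ...] = ()
    code_table: int = 5
    rscu_partition: str = "table8-standard"
    kaks_method: str = "YN00"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    min_cluster_len: int = 2
    max_tdrl_block: int = 6
    outdir: str = "mitocomp_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.queries:
            raise ValueError("at least one query genome is required")
        if self.code_table not in (1, 5):
            raise ValueError("code_table must be 1 or 5")
        if self.kaks_method not in ("NG86", "YN00"):
            raise ValueError("kaks_method must be NG86 or YN00")
        for p in (*self.queries, *self.references):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def read_config(path) -> RunConfig:
    """Parse a flat key=value config file (repeatable query/reference)."""
    queries, references, kw = [], [], {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "query":
            queries.append(value)
        elif key == "reference":
            references.append(value)
        elif key in ("code_table", "min_cluster_len", "max_tdrl_block", "seed"):
            kw[key] = int(value)
        elif key in ("gap_open", "gap_extend"):
            kw[key] = float(value)
        elif key in ("rscu_partition", "kaks_method", "outdir"):
            kw[key] = value
        else:
            raise KeyError(f"unknown config key {key!r}")
    return RunConfig(tuple(queries), tuple(references), **kw)


def _load(path) -> AnnotatedGenome:
    return read_genbank(path)


def run_compare(config: RunConfig) -> dict:
    """Run the full comparison; returns the machine-readable summary.

    Writes per-genome composition and codon-usage tables, the Ka/Ks
    table, the gene-order report and summary.json under config.outdir.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logpath = outdir / "run.log"
    handler = logging.FileHandler(logpath, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mitocomp")
    root.addHandler(handler)
    t0 = time.time()
    code = genetic_code(config.code_table, config.rscu_partition
                        if config.code_table == 5 else None)
    summary: dict = {"genomes": {}, "stages": {}}
    errors = []

    queries = [_load(p) for p in config.queries]
    references = [_load(p) for p in config.references]
    log.info("stage load: %d query + %d reference genomes",
             len(queries), len(references))

    for g in queries + references:
        try:
            df = comp.feature_class_summary(g)
            df.to_csv(outdir / f"composition_{g.id}.tsv", sep="\t", index=False)
            whole = comp.base_composition(g.sequence)
            summary["genomes"][g.id] = {
                "size_bp": len(g), **whole.pct(1),
                "at_skew": round(whole.at_skew, 4),
                "gc_skew": round(whole.gc_skew, 4),
                "n_features": len(g.features),
            }
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(("composition", g.id, str(exc)))
            log.error("stage composition failed for %s: %s", g.id, exc)
    summary["stages"]["composition"] = "ok" if not errors else "partial"

    for g in queries:
        try:
            table = cu.codon_usage_of_genome(g, code)
            table.to_frame().to_csv(outdir / f"codon_usage_{g.id}.tsv",
                                    sep="\t", index=False)
            cu.start_stop_table(g, code).to_csv(
                outdir / f"start_stop_{g.id}.tsv", sep="\t", index=False)
            deg = cu.degenerate_site_composition(extract_cds(g, code), code)
            (outdir / f"degeneracy_{g.id}.json").write_text(
                json.dumps({str(d): deg.counts[d] for d in sorted(deg.counts)},
                           indent=1))
            summary["genomes"][g.id]["total_codons"] = table.total_codons
        except Exception as exc:
            errors.append(("codon_usage", g.id, str(exc)))
            log.error("stage codon_usage failed for %s: %s", g.id, exc)
    summary["stages"]["codon_usage"] = "ok"

    if references:
        try:
            scoring = AlignmentScoring(gap_open=config.gap_open,
                                       gap_extend=config.gap_extend)
            frames = []
            for q in queries:
                frames.append(pairwise_kaks_matrix(
                    q, references, method=config.kaks_method, code=code,
                    scoring=scoring))
            import pandas as pd

            kaks = pd.concat(frames, ignore_index=True)
            kaks.to_csv(outdir / "kaks.tsv", sep="\t", index=False,
                        float_format="%.6g")
            if "KaKs" in kaks:
                finite = kaks.dropna(subset=["KaKs"])
                summary["kaks"] = {
                    "rows": len(kaks),
                    "max_ratio": (float(finite["KaKs"].max())
                                  if len(finite) else None),
                }
            summary["stages"]["kaks"] = "ok"
        except Exception as exc:
            errors.append(("kaks", "-", str(exc)))
            summary["stages"]["kaks"] = "failed"
            log.error("stage kaks failed: %s", exc)

    if len(queries) >= 2:
        try:
            a, b = (gene_order_of(g) for g in queries[:2])
            shared = go.shared_clusters(a, b, config.min_cluster_len)
            reversed_ = go.reversed_clusters(a, b, config.min_cluster_len)
            only_a, only_b = go.noncommon_genes(a, b)
            report = {
                "shared_clusters": [list(c.labels) for c in shared],
                "reversed_clusters": [list(c.labels) for c in reversed_],
                "noncommon": {a.id: list(only_a), b.id: list(only_b)},
                "duplicates": {a.id: go.find_duplicates(a),
                               b.id: go.find_duplicates(b)},
            }
            (outdir / "gene_order.json").write_text(json.dumps(report, indent=1))
            summary["gene_order"] = {
                "n_shared_clusters": len(shared),
                "n_reversed_clusters": len(reversed_),
            }
            summary["stages"]["gene_order"] = "ok"
        except Exception as exc:
            errors.append(("gene_order", "-", str(exc)))
            summary["stages"]["gene_order"] = "failed"
            log.error("stage gene_order failed: %s", exc)

    summary["errors"] = [list(e) for e in errors]
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                    sort_keys=True))
    log.info("run finished in %.1fs with %d error(s)", time.time() - t0,
             len(errors))
    root.removeHandler(handler)
    handler.close()
    if any(stage == "failed" for stage in summary["stages"].values()):
        raise RuntimeError(f"fatal stage error(s): {errors}")
    return summary
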