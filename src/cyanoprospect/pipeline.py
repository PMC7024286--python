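"""End-to-end orchestration of the three analysis stages.

``run_all`` drives taxonomy (p-distance delimitation on an aligned FASTA),
molecular networking (MGF + quantification table) and the growth-inhibition
assay (plate CSV) from a single :class:`RunConfig`, writing one report per
stage plus a run log with every resolved parameter. Stages are independent: a
failure in one is recorded and the others still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bioassay, specnet, taxonomy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageResult", "run_all"]


@dataclass
class RunConfig:
    """Paths and parameters for a full run; defaults are the study profile
    (cosine 0.7 / more-than-six matched peaks / top-10; 99% and 95% identity
    cutoffs; 100 bootstrap replicates; 50% activity threshold)."""

    # inputs (any stage whose inputs are None/missing is skipped)
    fasta: str | None = None
    newick: str | None = None  # optional external tree for monophyly checks
    mgf: str | None = None
    quant: str | None = None
    library_mgf: str | None = None
    plates: str | None = None
    sample_genus: str | None = None  # CSV: sample_id,genus

    # taxonomy parameters
    outgroup: str | None = None  # default: last sequence in the FASTA
    reference_ids: tuple = ()
    species_cutoff: float = taxonomy.SPECIES_CUTOFF
    genus_cutoff: float = taxonomy.GENUS_CUTOFF
    n_bootstrap: int = 100
    trim: tuple | None = None

    # networking parameters
    network: specnet.NetworkParams = field(default_factory=specnet.NetworkParams)

    # assay parameters
    activity_threshold: float = bioassay.ACTIVITY_THRESHOLD

    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Plain-text ``key = value`` config; unknown keys are rejected."""
        cfg = cls()
        net_fields = {f.name for f in dataclasses.fields(specnet.NetworkParams)}
        own_fields = {f.name: f for f in dataclasses.fields(cls)}
        for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in net_fields:
                current = getattr(cfg.network, key)
                setattr(cfg.network, key, _coerce(value, current))
            elif key in own_fields:
                setattr(cfg, key, _coerce(value, getattr(cfg, key)))
            else:
                raise ValueError(f"{path}:{line_no}: unknown key {key!r}")
        return cfg


def _coerce(value: str, template):
    if isinstance(template, bool):
        return value.lower() in ("1", "true", "yes", "on")
    if isinstance(template, int) and not isinstance(template, bool):
        return int(value)
    if isinstance(template, float):
        return float(value)
    if isinstance(template, tuple):
        return tuple(part.strip() for part in value.split(",") if part.strip())
    return value


@dataclass
class StageResult:
    name: str
    ok: bool
    detail: dict = field(default_factory=dict)
    error: str | None = None


def _resolved_params(cfg: RunConfig) -> dict:
    out = dataclasses.asdict(cfg)
    return out


def _run_taxonomy(cfg: RunConfig, outdir: Path) -> StageResult:
    if cfg.fasta is None or not Path(cfg.fasta).exists():
        return StageResult("taxonomy", False, error=f"missing FASTA: {cfg.fasta}")
    aln = taxonomy.AlignedSequences.from_fasta(cfg.fasta, trim=cfg.trim)
    outgroup = cfg.outgroup or aln.ids[-1]
    dm = taxonomy.distance_matrix(aln)
    tree = taxonomy.bootstrap_support(aln, n_reps=cfg.n_bootstrap, seed=cfg.seed,
                                      outgroup=outgroup)
    if cfg.newick:
        mono_tree = taxonomy.PhyloTree.from_newick(cfg.newick)
    else:
        mono_tree = tree
    delim = taxonomy.delimit(dm, mono_tree, reference_ids=cfg.reference_ids,
                             species_cutoff=cfg.species_cutoff,
                             genus_cutoff=cfg.genus_cutoff)
    dm.to_csv(outdir / "distance_matrix.csv")
    tree.to_newick(outdir / "tree.nwk")
    delim.to_csv(outdir / "delimitation.csv")
    return StageResult("taxonomy", True, {
        "n_sequences": len(aln.ids),
        "n_species_clusters": delim.n_species,
        "n_genus_clusters": delim.n_genera,
        "n_monophyletic_species": int(
            delim.frame.groupby("species_cluster")["monophyly_ok"].first().sum()
        ),
    })


def _run_network(cfg: RunConfig, outdir: Path) -> StageResult:
    if cfg.mgf is None or not Path(cfg.mgf).exists():
        return StageResult("network", False, error=f"missing MGF: {cfg.mgf}")
    spectra = specnet.read_mgf(cfg.mgf)
    if cfg.quant and Path(cfg.quant).exists():
        spectra = specnet.attach_quant(spectra, specnet.read_quant(cfg.quant))
    net = specnet.build_network(spectra, cfg.network)

    profile = None
    if cfg.sample_genus and Path(cfg.sample_genus).exists():
        mapping = pd.read_csv(cfg.sample_genus)
        profile = specnet.genus_intensity(
            net, dict(zip(mapping["sample_id"], mapping["genus"]))
        )

    hits: list[specnet.AnnotationHit] = []
    if cfg.library_mgf and Path(cfg.library_mgf).exists():
        lib_spectra = specnet.read_mgf(cfg.library_mgf)
        library = [(s.feature_id, s) for s in lib_spectra]
        p = cfg.network
        strict = specnet.library_search(spectra, library, p.library_score_min,
                                        p.library_min_matched, p.precursor_tol, p)
        strict_ids = {h.feature_id for h in strict}
        analog = [h for h in specnet.analog_search(spectra, library, p.library_score_min,
                                                   p.library_min_matched,
                                                   p.analog_max_delta, p)
                  if h.feature_id not in strict_ids]
        hits = strict + analog

    specnet.export_graphml(net, outdir / "network.graphml", profile=profile, hits=hits)
    summary = net.summary()
    summary["n_strict_hits"] = sum(h.match_type == "strict" for h in hits)
    summary["n_analog_hits"] = sum(h.match_type == "analog" for h in hits)
    with open(outdir / "network_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if hits:
        pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
            outdir / "annotations.csv", index=False
        )
    return StageResult("network", True, summary)


def _run_assay(cfg: RunConfig, outdir: Path) -> StageResult:
    if cfg.plates is None or not Path(cfg.plates).exists():
        return StageResult("assay", False, error=f"missing plate CSV: {cfg.plates}")
    readings = bioassay.read_plate_csv(cfg.plates)
    results = [bioassay.summarize(r, cfg.activity_threshold) for r in readings]
    table = bioassay.activity_table(results, cfg.activity_threshold)
    table.to_csv(outdir / "activity.csv")
    return StageResult("assay", True, {
        "n_readings": len(results),
        "n_active": sum(r.active for r in results),
    })


def run_all(cfg: RunConfig) -> dict:
    """Run every stage whose inputs exist; write reports and a run log.

    Returns ``{"stages": [StageResult...], "ok": all-stages-with-inputs-ok}``.
    The run log lists the fully resolved parameter set so each report is
    traceable to its exact configuration.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    for runner in (_run_taxonomy, _run_network, _run_assay):
        try:
            stages.append(runner(cfg, outdir))
        except Exception as exc:  # stage independence: record and continue
            name = runner.__name__.removeprefix("_run_")
            logger.error("stage %s failed: %s", name, exc)
            stages.append(StageResult(name, False, error=f"{type(exc).__name__}: {exc}"))

    log_lines = ["# cyanoprospect run log", "", "[parameters]"]
    for key, value in sorted(_resolved_params(cfg).items()):
        log_lines.append(f"{key} = {value}")
    log_lines += ["", "[stages]"]
    for s in stages:
        status = "ok" if s.ok else f"FAILED ({s.error})"
        log_lines.append(f"{s.name}: {status} {json.dumps(s.detail, sort_keys=True)}")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    attempted = [s for s in stages if not (s.error or "").startswith("missing")]
    return {"stages": stages, "ok": all(s.ok for s in attempted)}
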