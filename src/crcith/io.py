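"""Cohort file I/O and the end-to-end analysis pipeline.

Formats
-------
* per-sample somatic VCF v4.2 with AD-style ref/alt depths in the sample
  column (read through pysam; written as plain text);
* a tab-separated count matrix (one row per mutation: chrom, pos, ref, alt,
  context, gene, coding_class, then ``<sample>_ref`` / ``<sample>_alt``
  column pairs, germline included);
* a JSON cohort-truth file for simulated data;
* a YAML manifest naming the patient, the samples (label, role, area, file)
  and pipeline options.

The pipeline runs simulate/read -> presence matrix -> spectrum -> phylogeny
-> statistics and writes newick, spectrum, concordance, clone-block, purity
and distance tables plus one machine-readable JSON summary.  Stage timings go
to the log only, so reruns with the same seed produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from . import matrix as mx
from . import phylo as ph
from . import spectrum as sp
from . import stats as st
from .simulate import (
    Cohort,
    ClonePhylogeny,
    CohortTruth,
    MutationAssignment,
    ReadCounts,
    SampleSpec,
    SamplingDesign,
)

__all__ = [
    "Manifest",
    "ManifestSample",
    "PipelineConfig",
    "read_manifest",
    "read_cohort",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_sample_vcfs",
    "read_sample_vcfs",
    "write_truth_json",
    "read_truth_json",
    "write_presence_tsv",
    "run_pipeline",
]

logger = logging.getLogger("crcith")

_META_COLUMNS = ["chrom", "pos", "ref", "alt", "context", "gene", "coding_class"]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class ManifestSample:
    label: str
    role: str  # tumor | spheroid | lnm | germline
    area: Optional[str] = None
    path: Optional[str] = None


@dataclass
class Manifest:
    patient: str
    samples: list[ManifestSample]
    counts_tsv: Optional[str] = None
    options: dict = field(default_factory=dict)

    def validate(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate sample labels in manifest: {dupes}")
        germline = [s for s in self.samples if s.role == "germline"]
        if len(germline) != 1:
            raise ValueError(
                f"manifest must name exactly one germline sample, found {len(germline)}"
            )
        for s in self.samples:
            if s.role not in ("tumor", "spheroid", "lnm", "germline"):
                raise ValueError(f"sample {s.label!r}: unknown role {s.role!r}")
        # paired tumor/spheroid areas must be consistent (at most one of each per area)
        for role in ("tumor", "spheroid"):
            areas = [s.area for s in self.samples if s.role == role and s.area]
            if len(set(areas)) != len(areas):
                raise ValueError(f"manifest has duplicate {role} areas")

    @property
    def germline(self) -> ManifestSample:
        return next(s for s in self.samples if s.role == "germline")

    def pairing(self) -> dict[str, tuple[str, str]]:
        """area -> (biopsy label, spheroid label) for fully paired areas."""
        tumors = {s.area: s.label for s in self.samples if s.role == "tumor" and s.area}
        spheroids = {s.area: s.label for s in self.samples if s.role == "spheroid" and s.area}
        return {a: (tumors[a], spheroids[a]) for a in tumors if a in spheroids}


def read_manifest(path: Union[str, Path]) -> Manifest:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "samples" not in raw:
        raise ValueError(f"{path}: manifest must be a mapping with a 'samples' list")
    samples = [
        ManifestSample(
            label=s["label"],
            role=s["role"],
            area=s.get("area"),
            path=s.get("path"),
        )
        for s in raw["samples"]
    ]
    manifest = Manifest(
        patient=raw.get("patient", "patient"),
        samples=samples,
        counts_tsv=raw.get("counts_tsv"),
        options=raw.get("options", {}),
    )
    manifest.validate()
    return manifest


def write_manifest(manifest: Manifest, path: Union[str, Path]) -> None:
    raw = {
        "patient": manifest.patient,
        "samples": [
            {k: v for k, v in dataclasses.asdict(s).items() if v is not None}
            for s in manifest.samples
        ],
    }
    if manifest.counts_tsv:
        raw["counts_tsv"] = manifest.counts_tsv
    if manifest.options:
        raw["options"] = manifest.options
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# TSV count matrix
# ---------------------------------------------------------------------------


def write_counts_tsv(counts: ReadCounts, path: Union[str, Path]) -> None:
    out = counts.mutations.loc[:, [c for c in _META_COLUMNS if c in counts.mutations]].copy()
    for sample in list(counts.alt.columns):
        out[f"{sample}_ref"] = counts.ref[sample]
        out[f"{sample}_alt"] = counts.alt[sample]
    out.index.name = "mutation_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: Union[str, Path], germline: str = "germline") -> ReadCounts:
    table = pd.read_csv(path, sep="\t", index_col="mutation_id", dtype={"chrom": str})
    ref_cols = [c for c in table.columns if c.endswith("_ref")]
    samples = [c[:-4] for c in ref_cols]
    if germline not in samples:
        raise ValueError(f"{path}: no germline columns {germline}_ref/{germline}_alt")
    meta = table[[c for c in _META_COLUMNS if c in table.columns]].copy()
    ref = table[[f"{s}_ref" for s in samples]].astype(int)
    alt = table[[f"{s}_alt" for s in samples]].astype(int)
    ref.columns = alt.columns = samples
    return ReadCounts(ref=ref, alt=alt, mutations=meta, germline=germline)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=crcith
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CTX,Number=1,Type=String,Description="Reference trinucleotide context">
##INFO=<ID=CCLS,Number=1,Type=String,Description="Coding class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_sample_vcfs(counts: ReadCounts, out_dir: Union[str, Path]) -> dict[str, Path]:
    """One single-sample VCF v4.2 per column (germline included)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = counts.mutations
    paths: dict[str, Path] = {}
    contigs = sorted(set(meta["chrom"].astype(str)))
    for sample in list(counts.alt.columns):
        path = out_dir / f"{sample}.vcf"
        somatic = sample != counts.germline
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for contig in contigs:
                fh.write(f"##contig=<ID={contig}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
            )
            for mid, row in meta.iterrows():
                r = int(counts.ref.at[mid, sample])
                a = int(counts.alt.at[mid, sample])
                gt = "0/1" if (somatic and a > 0) else "0/0"
                info = f"GENE={row['gene']};CTX={row['context']};CCLS={row['coding_class']}"
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{mid}\t{row['ref']}\t{row['alt']}"
                    f"\t.\tPASS\t{info}\tGT:AD:DP\t{gt}:{r},{a}:{r + a}\n"
                )
        paths[sample] = path
    return paths


def _read_one_vcf(path: Union[str, Path]) -> pd.DataFrame:
    """Site records of one single-sample VCF as a DataFrame keyed by site."""
    rows = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        sample = list(vcf.header.samples)
        if len(sample) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF, found {sample}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) == 0:
                continue
            if len(rec.alts) > 1:
                warnings.warn(
                    f"{path}: multi-allelic site {rec.chrom}:{rec.pos}; "
                    "taking the first alternate"
                )
            ad = rec.samples[sample[0]].get("AD")
            if ad is None or len(ad) < 2:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AD ref/alt depths"
                )
            rows.append(
                {
                    "key": f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}",
                    "chrom": str(rec.chrom),
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "id": rec.id,
                    "gene": rec.info.get("GENE", "."),
                    "context": rec.info.get("CTX", "NNN"),
                    "coding_class": rec.info.get("CCLS", "missense"),
                    "ref_reads": int(ad[0]),
                    "alt_reads": int(ad[1]),
                }
            )
    return pd.DataFrame(rows)


def read_sample_vcfs(
    paths: Mapping[str, Union[str, Path]], germline: str
) -> ReadCounts:
    """Unify per-sample VCFs into one count matrix keyed by (chrom,pos,ref,alt).

    Sites absent from a sample's VCF default to zero depth with a warning
    summarising how many records were missing per sample.
    """
    if germline not in paths:
        raise ValueError(f"germline sample {germline!r} has no VCF in the manifest")
    frames = {s: _read_one_vcf(p) for s, p in paths.items()}
    all_keys: list[str] = []
    meta_rows: dict[str, dict] = {}
    for frame in frames.values():
        for _, row in frame.iterrows():
            if row["key"] not in meta_rows:
                all_keys.append(row["key"])
                meta_rows[row["key"]] = {
                    "mutation_id": row["id"] if row["id"] else row["key"],
                    "chrom": row["chrom"],
                    "pos": row["pos"],
                    "ref": row["ref"],
                    "alt": row["alt"],
                    "context": row["context"],
                    "gene": row["gene"],
                    "coding_class": row["coding_class"],
                }
    ids = [meta_rows[k]["mutation_id"] for k in all_keys]
    if len(set(ids)) != len(ids):  # fall back to site keys when ids collide
        ids = all_keys
        for k in all_keys:
            meta_rows[k]["mutation_id"] = k
    meta = pd.DataFrame([meta_rows[k] for k in all_keys]).set_index("mutation_id")

    ref = pd.DataFrame(0, index=meta.index, columns=list(paths))
    alt = pd.DataFrame(0, index=meta.index, columns=list(paths))
    key_to_id = {k: meta_rows[k]["mutation_id"] for k in all_keys}
    for sample, frame in frames.items():
        present = set()
        for _, row in frame.iterrows():
            mid = key_to_id[row["key"]]
            ref.at[mid, sample] = row["ref_reads"]
            alt.at[mid, sample] = row["alt_reads"]
            present.add(row["key"])
        n_missing = len(all_keys) - len(present)
        if n_missing:
            warnings.warn(
                f"sample {sample!r}: {n_missing} cohort sites absent from its VCF; "
                "treated as zero depth"
            )
    return ReadCounts(ref=ref, alt=alt, mutations=meta, germline=germline)


def read_cohort(manifest: Union[Manifest, str, Path]) -> tuple[ReadCounts, Manifest]:
    """Load a cohort's counts from the manifest's TSV matrix or sample VCFs."""
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    manifest.validate()
    germline = manifest.germline.label
    if manifest.counts_tsv:
        counts = read_counts_tsv(manifest.counts_tsv, germline=germline)
    else:
        paths = {}
        for s in manifest.samples:
            if s.path is None:
                raise ValueError(f"sample {s.label!r} has neither a VCF path nor a counts_tsv")
            if not Path(s.path).exists():
                raise FileNotFoundError(f"sample {s.label!r}: file not found: {s.path}")
            paths[s.label] = s.path
        counts = read_sample_vcfs(paths, germline=germline)
    return counts, manifest


# ---------------------------------------------------------------------------
# Truth JSON
# ---------------------------------------------------------------------------


def write_truth_json(truth: CohortTruth, path: Union[str, Path]) -> None:
    payload = {
        "clone_parent": dict(truth.tree.parent),
        "mutations": truth.assignment.table.reset_index().to_dict(orient="records"),
        "samples": [
            {
                "name": s.name,
                "role": s.role,
                "area": s.area,
                "purity": s.purity,
                "mixture": dict(s.mixture),
            }
            for s in truth.design.samples
        ],
        "design": {
            "mean_depth": truth.design.mean_depth,
            "depth_dispersion": truth.design.depth_dispersion,
            "error_rate": truth.design.error_rate,
            "germline_name": truth.design.germline_name,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path: Union[str, Path]) -> CohortTruth:
    with open(path) as fh:
        payload = json.load(fh)
    tree = ClonePhylogeny(payload["clone_parent"])
    table = pd.DataFrame(payload["mutations"]).set_index("mutation_id")
    assignment = MutationAssignment(table)
    design = SamplingDesign(
        samples=[
            SampleSpec(
                name=s["name"], role=s["role"], area=s["area"],
                purity=s["purity"], mixture=s["mixture"],
            )
            for s in payload["samples"]
        ],
        **payload["design"],
    )
    sample_names = [s.name for s in design.samples]
    desc = {c: tree.descendants(c) for c in tree.nodes}
    frac = np.array(
        [
            [
                sum(f for c, f in spec.mixture.items() if c in desc[b])
                for spec in design.samples
            ]
            for b in table["branch"]
        ]
    )
    purity = np.array([s.purity for s in design.samples])
    return CohortTruth(
        tree=tree,
        assignment=assignment,
        design=design,
        incidence=pd.DataFrame(frac > 0, index=table.index, columns=sample_names),
        expected_af=pd.DataFrame(0.5 * purity[None, :] * frac, index=table.index, columns=sample_names),
        purity=pd.Series(purity, index=sample_names),
    )


# ---------------------------------------------------------------------------
# Presence matrix TSV
# ---------------------------------------------------------------------------


def write_presence_tsv(presence: mx.PresenceMatrix, path: Union[str, Path]) -> None:
    """Mutations-as-rows TSV: metadata, sharing, then per-sample AF and state."""
    out = presence.mutations.copy()
    for sample in presence.samples:
        out[f"{sample}_af"] = presence.af[sample].round(4)
        out[f"{sample}_state"] = presence.states[sample]
    out.index.name = "mutation_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    seed: int = 0
    min_depth: int = 10
    mask_mode: str = "drop"  # heatmap-matrix behaviour; tree scoring uses "missing"
    exhaustive_limit: int = ph.DEFAULT_EXHAUSTIVE_LIMIT
    restarts: int = 10
    coding_only: bool = False
    gene_list: Optional[str] = None

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(
    counts: ReadCounts,
    manifest: Manifest,
    config: PipelineConfig,
    out_dir: Union[str, Path],
) -> dict:
    """Run matrix -> spectrum -> phylogeny -> statistics and write reports.

    Returns the JSON-serialisable summary that is also written to
    ``summary.json``.  Fully deterministic given the config seed; stage
    timings are logged to stderr only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- presence matrix ---------------------------------------------------
    base = mx.call_presence(counts)
    base = mx.classify_sharing(base)
    if config.gene_list:
        base = mx.annotate_genes(base, config.gene_list)
    pm_heat = mx.apply_coverage_mask(counts=counts, presence=base,
                                     min_depth=config.min_depth, mode=config.mask_mode)
    pm_tree = mx.apply_coverage_mask(counts=counts, presence=base,
                                     min_depth=config.min_depth, mode="missing")
    write_presence_tsv(pm_heat, out_dir / "presence.tsv")
    filter_counts = {
        "input_mutations": int(counts.alt.shape[0]),
        "germline_excluded": len(base.germline_excluded),
        "uncalled": len(base.uncalled),
        "mask_dropped": len(pm_heat.mask_dropped),
        "retained_heatmap": int(pm_heat.states.shape[0]),
        "retained_tree": int(pm_tree.states.shape[0]),
    }
    logger.info("filters: %s", filter_counts)
    t0 = _stage("matrix", t0)

    # --- mutational spectrum ----------------------------------------------
    classified = sp.classify_mutations(base.mutations)
    table = sp.spectrum_table(classified)
    table.to_csv(out_dir / "spectrum.tsv", sep="\t")
    try:
        test = sp.cpg_enrichment_test(table)
        spectrum_test = {
            "statistic": test.statistic,
            "df": test.df,
            "pvalue": test.pvalue,
        }
    except ValueError as exc:
        spectrum_test = {"error": str(exc)}
    with open(out_dir / "spectrum_test.json", "w") as fh:
        json.dump(spectrum_test, fh, indent=1, sort_keys=True)
    t0 = _stage("spectrum", t0)

    # --- phylogeny ----------------------------------------------------------
    ptree = ph.best_tree(
        pm_tree,
        method="auto",
        seed=config.seed,
        exhaustive_limit=config.exhaustive_limit,
        restarts=config.restarts,
    )
    (out_dir / "tree.nwk").write_text(ph.to_newick(ptree) + "\n")
    support_rows = [
        {
            "clade": ",".join(sorted(clade)),
            "n_mutations": len(muts),
            "is_trunk": clade == ptree.trunk,
        }
        for clade, muts in ptree.edge_mutations.items()
    ]
    pd.DataFrame(support_rows).to_csv(out_dir / "edge_support.tsv", sep="\t", index=False)
    pd.DataFrame({"mutation_id": list(ptree.homoplasies)}).to_csv(
        out_dir / "homoplasy.tsv", sep="\t", index=False
    )
    t0 = _stage("phylogeny", t0)

    # --- statistics ---------------------------------------------------------
    dist = st.binary_distance_matrix(pm_heat)
    dist.to_csv(out_dir / "distance.tsv", sep="\t")
    link = st.average_linkage(dist)
    pd.DataFrame(
        link.merges, columns=["cluster_a", "cluster_b", "height", "size"]
    ).to_csv(out_dir / "linkage.tsv", sep="\t", index=False)

    summary: dict = {
        "patient": manifest.patient,
        "seed": config.seed,
        "config_digest": config.digest(),
        "filters": filter_counts,
        "spectrum_test": spectrum_test,
        "tree": {
            "newick": ph.to_newick(ptree),
            "score": ptree.score,
            "n_characters": ptree.n_characters,
            "n_homoplasies": len(ptree.homoplasies),
            "method": ptree.method,
        },
        "heatmap_leaf_order": list(link.leaf_order),
    }

    pairing = manifest.pairing()
    if pairing:
        report = st.concordance_stats(base, pairing, coding_only=config.coding_only)
        report.per_area.to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
        report.per_sample.to_csv(out_dir / "private_fractions.tsv", sep="\t", index=False)
        matched, cross, test = st.matched_pair_distance_test(ptree, pairing)
        summary["concordance"] = {
            "mean_concordant_frac": float(report.per_area["concordant_frac"].mean()),
            "mean_private_fraction": float(report.per_sample["private_fraction"].mean()),
            "mean_pairwise_private_frac": float(
                report.per_area["pairwise_private_frac"].mean()
            ),
        }
        summary["matched_vs_cross"] = {
            "matched_distances": matched,
            "cross_distances": cross,
            "pvalue": test.pvalue,
            "method": test.method,
        }

    lnm_labels = [s.label for s in manifest.samples if s.role == "lnm"]
    tumor_labels = [s.label for s in manifest.samples if s.role == "tumor"]
    spheroid_labels = [s.label for s in manifest.samples if s.role == "spheroid"]
    if lnm_labels and tumor_labels:
        patterns = {
            "nonmetastatic": st.BlockPattern(
                present_in_all=frozenset(tumor_labels + spheroid_labels),
                absent_in_all=frozenset(lnm_labels),
            ),
        }
        for area, (biopsy, spheroid) in (pairing or {}).items():
            others = [t for t in tumor_labels if t != biopsy]
            patterns[f"metastatic_seed_{area}"] = st.BlockPattern(
                present_in_all=frozenset(lnm_labels + [biopsy]),
                absent_in_all=frozenset(others),
            )
        blocks = st.clone_blocks(base, patterns)
        with open(out_dir / "clone_blocks.json", "w") as fh:
            json.dump({k: list(v) for k, v in blocks.items()}, fh, indent=1, sort_keys=True)
        summary["clone_blocks"] = {k: len(v) for k, v in blocks.items()}

    truncal_ids = list(
        base.mutations.index[base.mutations["carrier_count"] >= base.n_samples - 1]
    )
    purity = st.purity_from_af(base.af, truncal_ids)
    purity.to_frame().to_csv(out_dir / "purity.tsv", sep="\t")
    summary["purity"] = {k: (None if pd.isna(v) else round(float(v), 4))
                         for k, v in purity.items()}
    biopsy_p, spheroid_p = [], []
    for area, (biopsy, spheroid) in (pairing or {}).items():
        if pd.notna(purity.get(biopsy)) and pd.notna(purity.get(spheroid)):
            biopsy_p.append(float(purity[biopsy]))
            spheroid_p.append(float(purity[spheroid]))
    if biopsy_p:
        ptest = st.signed_rank_test(spheroid_p, biopsy_p)
        summary["purity_spheroid_vs_biopsy"] = {
            "pvalue": ptest.pvalue,
            "method": ptest.method,
        }
    t0 = _stage("statistics", t0)

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
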