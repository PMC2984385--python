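"""File formats: genetic maps, phased haplotypes, phenotypes, scan results.

Everything is plain TSV (UTF-8, '.' decimal separator):

* map: ``marker_id  position_cM`` (header line);
* haplotypes: ``individual_id  role  sire_id  alleles`` where ``role`` is
  ``sire`` (two rows per sire, chromosome 1 first), ``progeny_pat`` or
  ``progeny_mat``, and ``alleles`` is a 0/1 string in map order;
* phenotypes: ``individual_id  sire_id  phenotype``.

A phased VCF (``0|1`` genotypes) can replace the haplotype TSV; the first
allele of each genotype is chromosome 1 for sires and the paternally
transmitted chromosome for progeny.  All writes are atomic (temporary file
then rename) and every output directory gets a JSON run manifest.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .simdesign import HalfSibDesign, Scenario

__all__ = [
    "read_map", "write_map", "write_design", "read_design",
    "read_design_vcf", "write_scan_result", "write_manifest",
    "read_scenario_yaml",
]


def _atomic_write(path, text: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_map(gmap: GeneticMap, path):
    lines = ["marker_id\tposition_cM"]
    lines += [f"{m}\t{p:.10g}" for m, p in zip(gmap.marker_ids, gmap.positions)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_map(path, qtl_position: float | None = None) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    if list(df.columns) != ["marker_id", "position_cM"]:
        raise ValueError(f"{path}: expected columns marker_id, position_cM")
    return GeneticMap(df["position_cM"].to_numpy(float),
                      tuple(df["marker_id"]), qtl_position)


def _hap_str(h: np.ndarray) -> str:
    return "".join(str(int(a)) for a in h)


def write_design(design: HalfSibDesign, outdir, scenario: Scenario | None = None,
                 seed=None):
    """Write map/haplotypes/phenotypes/truth TSVs plus a run manifest."""
    outdir = Path(outdir)
    write_map(design.gmap, outdir / "map.tsv")

    hap_lines = ["individual_id\trole\tsire_id\talleles"]
    truth_lines = ["individual_id\trole\tqtl_allele_1\tqtl_allele_2"]
    for i in range(design.n_sires):
        for k in (0, 1):
            hap_lines.append(f"S{i + 1}\tsire\t.\t{_hap_str(design.sire_haps[i, k])}")
        if design.true_sire_qtl is not None:
            q = design.true_sire_qtl[i]
            truth_lines.append(f"S{i + 1}\tsire\t{q[0]}\t{q[1]}")
    phen_lines = ["individual_id\tsire_id\tphenotype"]
    for j in range(design.n_progeny):
        pid, sid = f"P{j + 1}", f"S{design.sire_of[j] + 1}"
        hap_lines.append(f"{pid}\tprogeny_pat\t{sid}\t{_hap_str(design.pat_haps[j])}")
        hap_lines.append(f"{pid}\tprogeny_mat\t{sid}\t{_hap_str(design.mat_haps[j])}")
        phen_lines.append(f"{pid}\t{sid}\t{design.y[j]:.10g}")
        if design.true_pat_qtl is not None:
            truth_lines.append(
                f"{pid}\tprogeny\t{design.true_pat_qtl[j]}\t{design.true_mat_qtl[j]}")
    _atomic_write(outdir / "haplotypes.tsv", "\n".join(hap_lines) + "\n")
    _atomic_write(outdir / "phenotypes.tsv", "\n".join(phen_lines) + "\n")
    _atomic_write(outdir / "truth.tsv", "\n".join(truth_lines) + "\n")
    write_manifest(outdir / "manifest.json", scenario=scenario, seed=seed,
                   true_qtl_cM=design.gmap.qtl_position)


def _parse_alleles(s: str, n_markers: int, lineno: int, path) -> np.ndarray:
    if len(s) != n_markers or set(s) - {"0", "1"}:
        raise ValueError(
            f"{path}:{lineno}: allele string must be {n_markers} characters "
            f"over {{0,1}} (got {len(s)})")
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


def read_design(map_path, haps_path, phen_path) -> HalfSibDesign:
    """Read and cross-validate a design from the three TSV files."""
    gmap = read_map(map_path)
    m = gmap.n_markers

    phen = pd.read_csv(phen_path, sep="\t", dtype={"individual_id": str, "sire_id": str})
    if list(phen.columns) != ["individual_id", "sire_id", "phenotype"]:
        raise ValueError(f"{phen_path}: expected columns individual_id, sire_id, phenotype")
    if phen["individual_id"].duplicated().any():
        dup = phen.loc[phen["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"{phen_path}: duplicated individual id {dup!r}")

    sire_rows: dict = {}
    pat_rows: dict = {}
    mat_rows: dict = {}
    prog_sire: dict = {}
    with open(haps_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["individual_id", "role", "sire_id", "alleles"]:
            raise ValueError(f"{haps_path}:1: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{haps_path}:{lineno}: expected 4 columns")
            ind, role, sire_id, alleles = parts
            h = _parse_alleles(alleles, m, lineno, haps_path)
            if role == "sire":
                sire_rows.setdefault(ind, []).append(h)
                if len(sire_rows[ind]) > 2:
                    raise ValueError(f"{haps_path}:{lineno}: sire {ind!r} has >2 haplotypes")
            elif role in ("progeny_pat", "progeny_mat"):
                target = pat_rows if role == "progeny_pat" else mat_rows
                if ind in target:
                    raise ValueError(f"{haps_path}:{lineno}: duplicated {role} for {ind!r}")
                target[ind] = h
                prog_sire.setdefault(ind, sire_id)
                if prog_sire[ind] != sire_id:
                    raise ValueError(f"{haps_path}:{lineno}: conflicting sire for {ind!r}")
            else:
                raise ValueError(f"{haps_path}:{lineno}: unknown role {role!r}")

    sire_ids = sorted(sire_rows)
    for s, hs in sire_rows.items():
        if len(hs) != 2:
            raise ValueError(f"{haps_path}: sire {s!r} needs exactly 2 haplotype rows")
    sire_index = {s: k for k, s in enumerate(sire_ids)}

    prog_ids = list(phen["individual_id"])
    missing = set(prog_ids) - set(pat_rows) or set(prog_ids) - set(mat_rows)
    if missing:
        raise ValueError(f"{haps_path}: missing haplotypes for progeny {sorted(missing)[:3]}")
    for pid, sid in zip(prog_ids, phen["sire_id"]):
        if sid not in sire_index:
            raise ValueError(f"{phen_path}: progeny {pid!r} references unknown sire {sid!r}")
        if prog_sire.get(pid, sid) != sid:
            raise ValueError(f"{phen_path}: sire mismatch for progeny {pid!r}")

    design = HalfSibDesign(
        gmap=gmap,
        sire_haps=np.array([sire_rows[s] for s in sire_ids], dtype=np.int8),
        sire_of=np.array([sire_index[s] for s in phen["sire_id"]]),
        pat_haps=np.array([pat_rows[p] for p in prog_ids], dtype=np.int8),
        mat_haps=np.array([mat_rows[p] for p in prog_ids], dtype=np.int8),
        y=phen["phenotype"].to_numpy(float),
    )
    return design.validate()


def read_design_vcf(map_path, vcf_path, phen_path) -> HalfSibDesign:
    """Design from a phased VCF plus map and phenotype TSVs.

    Samples are matched by id; ids appearing in the phenotype file's
    ``sire_id`` column are sires.  Genotypes must be phased (``0|1``); the
    first allele is chromosome 1 (sires) / the paternal chromosome
    (progeny).  Sites are matched to the map by the VCF ID field.
    """
    from cyvcf2 import VCF

    gmap = read_map(map_path)
    phen = pd.read_csv(phen_path, sep="\t", dtype={"individual_id": str, "sire_id": str})
    sire_ids = sorted(set(phen["sire_id"]))
    prog_ids = list(phen["individual_id"])

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    needed = set(sire_ids) | set(prog_ids)
    if needed - set(samples):
        raise ValueError(f"{vcf_path}: missing samples {sorted(needed - set(samples))[:3]}")
    col = {s: k for k, s in enumerate(samples)}
    marker_row = {mid: r for r, mid in enumerate(gmap.marker_ids)}
    h1 = np.full((len(samples), gmap.n_markers), -1, dtype=np.int8)
    h2 = np.full((len(samples), gmap.n_markers), -1, dtype=np.int8)
    for var in vcf:
        if var.ID not in marker_row:
            continue
        r = marker_row[var.ID]
        gt = np.array(var.genotypes)  # (n_samples, 3): allele1, allele2, phased
        if np.any(gt[:, 2] == 0):
            raise ValueError(f"{vcf_path}: unphased genotype at {var.ID}; phased GT required")
        h1[:, r] = gt[:, 0]
        h2[:, r] = gt[:, 1]
    if (h1 < 0).any():
        miss = [gmap.marker_ids[r] for r in np.unique(np.where(h1 < 0)[1])][:3]
        raise ValueError(f"{vcf_path}: markers missing from the VCF: {miss}")

    sire_index = {s: k for k, s in enumerate(sire_ids)}
    design = HalfSibDesign(
        gmap=gmap,
        sire_haps=np.stack([np.stack([h1[col[s]], h2[col[s]]]) for s in sire_ids]),
        sire_of=np.array([sire_index[s] for s in phen["sire_id"]]),
        pat_haps=np.stack([h1[col[p]] for p in prog_ids]),
        mat_haps=np.stack([h2[col[p]] for p in prog_ids]),
        y=phen["phenotype"].to_numpy(float),
    )
    return design.validate()


def write_scan_result(result, path):
    """Per-position scan table: position, statistic, winning haplotype, extras."""
    cols = {"position_cM": result.positions, "statistic": result.statistics}
    if result.best_haplotype is not None:
        cols["best_haplotype"] = result.best_haplotype
    for key in ("alpha_hat", "pi_q0_hat"):
        if key in result.extras:
            cols[key] = result.extras[key]
    df = pd.DataFrame(cols)
    _atomic_write(path, df.to_csv(sep="\t", index=False))


def write_manifest(path, **fields):
    """JSON run manifest (config, seed, package version) beside the outputs."""
    from . import __version__

    payload = {"ldlmap_version": __version__}
    for k, v in fields.items():
        if isinstance(v, Scenario):
            v = asdict(v)
        payload[k] = v
    _atomic_write(path, json.dumps(payload, indent=2, default=str) + "\n")


def read_scenario_yaml(path) -> Scenario:
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    known = set(Scenario.__dataclass_fields__)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"{path}: unknown scenario fields {sorted(unknown)}")
    return Scenario(**cfg)
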