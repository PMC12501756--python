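"""Readers and writers for the standard input formats.

Supported inputs:

* **Phased VCF** — only ``|``-phased GT fields are accepted; ``/``-separated
  or missing genotypes and multi-allelic sites are rejected with the
  offending record named.  The VCF REF allele maps to the internal
  "reference" coding (allele value 1).
* **Haplotype table** — a plain TSV with a ``sample`` column and one column
  per marker holding VCF-style phased calls ``0|1`` (0 = reference).
* **PLINK .map** — 4 columns (chromosome, marker id, cM, bp); the cM column
  is authoritative and divided by 100 to Morgans on read.
* **Effects table** — header ``marker<TAB>trait1[<TAB>trait2...]``, one row
  per marker.

Marker order always follows the map; genotype and effects files are
cross-validated against it.  Every writer/reader pair round-trips
bit-identically on its own output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    GeneticMap,
    MarkerEffects,
    PhasedGenotypes,
    haldane,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_phased",
    "read_map",
    "read_effects",
    "write_haplotypes",
    "write_matrix",
    "read_matrix",
    "make_fixtures",
]

# Worked three-marker example: two parents, adjacent recombination
# fractions (0.1, 0.2), effects (1, 0.2, 0.02).  The first parent carries
# the reference allele on its whole first haplotype (1-1-1/2-2-2 in the
# 1/2 allele notation); the second carries 1-2-1/2-1-2.
FIXTURE_THETA = (0.1, 0.2)
FIXTURE_EFFECTS = (1.0, 0.2, 0.02)
FIXTURE_HAPLOTYPES = {
    "parent1": ([1, 1, 1], [0, 0, 0]),
    "parent2": ([1, 0, 1], [0, 1, 0]),
}


def _parse_gt(token: str, where: str) -> tuple[int, int]:
    if "/" in token:
        raise ValueError(f"unphased genotype {token!r} at {where}")
    parts = token.split("|")
    if len(parts) != 2 or not all(p in ("0", "1") for p in parts):
        raise ValueError(f"malformed phased genotype {token!r} at {where}")
    # VCF REF (code 0) is the internal reference allele (value 1)
    return tuple(1 - int(p) for p in parts)


def read_phased(path, gmap: GeneticMap | None = None) -> PhasedGenotypes:
    """Read phased genotypes from a VCF (.vcf) or haplotype table (.tsv)."""
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf(path, gmap)
    return _read_hap_table(path, gmap)


def _read_vcf(path: Path, gmap: GeneticMap | None) -> PhasedGenotypes:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    rows, marker_ids = [], []
    for v in vcf:
        mid = v.ID or f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic site {mid} at {v.CHROM}:{v.POS}"
            )
        calls = np.array(v.genotypes)  # (samples, 3): a1, a2, phased
        for s, (a1, a2, phased) in zip(samples, calls):
            if a1 < 0 or a2 < 0:
                raise ValueError(
                    f"missing genotype at {mid} ({v.CHROM}:{v.POS}), "
                    f"sample {s}"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype at {mid} ({v.CHROM}:{v.POS}), "
                    f"sample {s}"
                )
        # VCF REF (code 0) is the internal reference allele (value 1)
        rows.append(1 - calls[:, :2])
        marker_ids.append(mid)
    vcf.close()
    # rows: (markers, samples, 2) -> (samples, 2, markers)
    hap = np.array(rows, dtype=np.int8).transpose(1, 2, 0)
    geno = PhasedGenotypes(hap, samples)
    return _align_to_map(geno, np.array(marker_ids), gmap)


def _read_hap_table(path: Path, gmap: GeneticMap | None) -> PhasedGenotypes:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column must be 'sample'")
    samples = df["sample"].to_numpy()
    markers = np.array(df.columns[1:])
    hap = np.empty((len(samples), 2, len(markers)), dtype=np.int8)
    for k, mid in enumerate(markers):
        for i, token in enumerate(df[mid]):
            hap[i, :, k] = _parse_gt(
                token, f"marker {mid}, sample {samples[i]}"
            )
    geno = PhasedGenotypes(hap, samples)
    return _align_to_map(geno, markers, gmap)


def _align_to_map(geno: PhasedGenotypes, marker_ids: np.ndarray,
                  gmap: GeneticMap | None) -> PhasedGenotypes:
    if gmap is None:
        return geno
    order = {m: k for k, m in enumerate(marker_ids)}
    missing = [m for m in gmap.marker_id if m not in order]
    extra = [m for m in marker_ids if m not in set(gmap.marker_id)]
    if missing or extra:
        raise ValueError(
            f"marker mismatch with map: missing {missing[:5]}, "
            f"unknown {extra[:5]}"
        )
    idx = np.array([order[m] for m in gmap.marker_id])
    return PhasedGenotypes(geno.haplotypes[:, :, idx], geno.sample_id,
                           geno.sex)


def read_map(path) -> GeneticMap:
    """Read a PLINK .map file (chrom, marker, cM, bp); cM -> Morgans."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cM", "bp"], dtype=str,
                     comment="#")
    return GeneticMap(
        df["chrom"].to_numpy(),
        df["cM"].astype(float).to_numpy() / 100.0,
        df["marker"].to_numpy(),
    )


def read_effects(path, gmap: GeneticMap | None = None) -> MarkerEffects:
    """Read a marker-effects table (marker column + one column per trait)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "marker":
        raise ValueError(f"{path}: first column must be 'marker'")
    traits = tuple(df.columns[1:])
    if not traits:
        raise ValueError(f"{path}: no trait columns")
    if df[list(traits)].isna().any().any():
        raise ValueError(f"{path}: empty effect entries")
    markers = df["marker"].to_numpy()
    values = df[list(traits)].to_numpy(dtype=float).T
    if gmap is not None:
        order = {m: k for k, m in enumerate(markers)}
        bad = [m for m in gmap.marker_id if m not in order]
        if bad or len(markers) != gmap.n_markers:
            raise ValueError(f"effects/map marker mismatch: {bad[:5]}")
        idx = np.array([order[m] for m in gmap.marker_id])
        values = values[:, idx]
    return MarkerEffects(values, traits)


def write_haplotypes(geno: PhasedGenotypes, gmap: GeneticMap, path,
                     header_comment: str | None = None):
    """Write a phased haplotype table readable by :func:`read_phased`."""
    # internal allele 1 = reference = VCF code 0
    codes = 1 - geno.haplotypes
    cells = np.char.add(
        np.char.add(codes[:, 0, :].astype(str), "|"),
        codes[:, 1, :].astype(str),
    )
    df = pd.DataFrame(cells, columns=list(gmap.marker_id))
    df.insert(0, "sample", geno.sample_id)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_matrix(matrix: np.ndarray, entities, path,
                 header_comment: str | None = None):
    """Write a square matrix with entity-id header row and column."""
    labels = ["|".join(map(str, e)) if isinstance(e, tuple) else str(e)
              for e in entities]
    df = pd.DataFrame(np.asarray(matrix), index=labels, columns=labels)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="entity")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`; returns
    (values, entities)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.to_numpy(dtype=float), tuple(df.columns)


def make_fixtures(target_dir) -> dict:
    """Write the two-parent, three-marker worked-example dataset.

    Emits ``haplotypes.tsv``, ``markers.map``, ``effects.tsv`` and a README
    stating the expected outputs (gamete MSVs 0.3461 and 0.1837, pairwise
    similarity 0.2449, standardised similarity ~0.9714).  Returns the file
    paths.
    """
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    pos_cm = np.concatenate(
        [[0.0], np.cumsum(haldane(np.array(FIXTURE_THETA))) * 100.0]
    )
    markers = [f"m{k + 1}" for k in range(3)]

    map_path = target / "markers.map"
    with open(map_path, "w") as fh:
        for k, (mid, cm) in enumerate(zip(markers, pos_cm)):
            fh.write(f"1\t{mid}\t{cm:.10f}\t{k + 1}\n")

    hap_path = target / "haplotypes.tsv"
    gmap = read_map(map_path)
    hap = np.array([
        np.stack([h1, h2])
        for h1, h2 in FIXTURE_HAPLOTYPES.values()
    ], dtype=np.int8)
    geno = PhasedGenotypes(hap, np.array(list(FIXTURE_HAPLOTYPES)))
    write_haplotypes(geno, gmap, hap_path,
                     header_comment="three-marker worked example")

    eff_path = target / "effects.tsv"
    with open(eff_path, "w") as fh:
        fh.write("marker\ttrait\n")
        for mid, m in zip(markers, FIXTURE_EFFECTS):
            fh.write(f"{mid}\t{m}\n")

    readme = target / "README.txt"
    readme.write_text(
        "Two-parent, three-marker worked example.\n"
        "Adjacent recombination fractions: 0.1, 0.2 (Haldane map).\n"
        "Marker effects: 1, 0.2, 0.02.\n"
        "Expected outputs:\n"
        "  gamete MSV parent1 = 0.3461\n"
        "  gamete MSV parent2 = 0.1837\n"
        "  pairwise similarity = 0.2449\n"
        "  standardised similarity k12 = 0.2449/sqrt(0.3461*0.1837) "
        "= 0.9714\n"
        "  zygote MSV (parent1 x parent2) = 0.5298\n"
    )
    return {
        "haplotypes": hap_path,
        "map": map_path,
        "effects": eff_path,
        "readme": readme,
    }
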