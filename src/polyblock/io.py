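"""Delimited-text readers and writers for the haplotyping pipeline.

File dialects (tab-separated unless noted):

* dosage matrix — header row of individual ids, first column marker id,
  entries 0..ploidy or ``NA``;
* haploblocks — two columns (block, marker), marker order within a block is
  the file order;
* full-sib families — one line per family: family id, parent1, parent2,
  then the offspring ids;
* pedigree — three columns (individual, parent1, parent2), ``NA`` for an
  unknown parent;
* truth set — three columns (block, individual, haplotype codes joined by
  ``/``), as written by the simulator;
* haplotype dosages (output) — per block: rows = haplotype codes observed
  in the block, columns = individuals, entries are haplotype dosages
  summing to ploidy per assigned individual, ``NA`` columns for unassigned.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fs import FSFamily
from .pipeline import AssignmentResult, PopulationStructure

NA = "NA"


def read_dosage_matrix(path, sep: str = "\t", missing: str = NA) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[missing])
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate marker or individual ids in dosage matrix")
    return df


def write_dosage_matrix(df: pd.DataFrame, path, sep: str = "\t", missing: str = NA) -> None:
    out = df.copy()
    out.index.name = "marker"
    out.to_csv(path, sep=sep, na_rep=missing, float_format="%.0f")


def read_haploblocks(path, sep: str = "\t") -> dict[str, list[str]]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("haploblock file needs columns (block, marker)")
    blocks: dict[str, list[str]] = {}
    for b, m in zip(df.iloc[:, 0], df.iloc[:, 1]):
        blocks.setdefault(b, []).append(m)
    return blocks


def write_haploblocks(blocks: Mapping[str, list[str]], path, sep: str = "\t") -> None:
    rows = [(b, m) for b in blocks for m in blocks[b]]
    pd.DataFrame(rows, columns=["block", "marker"]).to_csv(path, sep=sep, index=False)


def read_fs_families(path) -> PopulationStructure:
    fams = []
    for line in Path(path).read_text().splitlines():
        fields = line.split()
        if not fields or fields[0].startswith("#"):
            continue
        if len(fields) < 4:
            raise ValueError(f"family line needs id, 2 parents, >=1 offspring: {line!r}")
        fams.append(FSFamily(fields[0], fields[1], fields[2], tuple(fields[3:])))
    return PopulationStructure(fams)


def write_fs_families(structure: PopulationStructure, path) -> None:
    lines = [
        "\t".join([f.name, f.parent1, f.parent2, *f.offspring])
        for f in structure.families
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_pedigree(path, sep: str = "\t") -> dict[str, tuple[str | None, str | None]]:
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=[NA])
    ped = {}
    for _, row in df.iterrows():
        p1 = None if pd.isna(row.iloc[1]) else str(row.iloc[1])
        p2 = None if pd.isna(row.iloc[2]) else str(row.iloc[2])
        ped[str(row.iloc[0])] = (p1, p2)
    return ped


def pedigree_from_structure(structure: PopulationStructure) -> dict:
    return {
        o: (f.parent1, f.parent2) for f in structure.families for o in f.offspring
    }


def write_pedigree(ped: Mapping[str, tuple], path, sep: str = "\t") -> None:
    rows = [(i, p1 or NA, p2 or NA) for i, (p1, p2) in ped.items()]
    pd.DataFrame(rows, columns=["individual", "parent1", "parent2"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# results


def hapdos_frame(result: AssignmentResult, block: str) -> pd.DataFrame:
    """Haplotype-dosage matrix of one block (haplotype codes x individuals)."""
    br = result.blocks[block]
    codes = sorted(br.haplotypes_used)
    indivs = list(br.assignments)
    data = np.full((len(codes), len(indivs)), np.nan)
    pos = {c: i for i, c in enumerate(codes)}
    for j, indiv in enumerate(indivs):
        hc = br.assignments[indiv]
        if hc is None:
            continue
        data[:, j] = 0
        for c in hc:
            data[pos[c], j] += 1
    return pd.DataFrame(data, index=pd.Index(codes, name="haplotype"), columns=indivs)


def write_results(result: AssignmentResult, outdir, sep: str = "\t") -> None:
    """One haplotype-dosage matrix per block plus a family-status table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    status_rows = []
    for bname, br in result.blocks.items():
        if br.error:
            status_rows.append({"block": bname, "family": NA, "status": f"error:{br.error}"})
            continue
        hapdos_frame(result, bname).to_csv(
            outdir / f"{bname}_hapdos.tsv", sep=sep, na_rep=NA, float_format="%.0f"
        )
        for fam, status in br.family_status.items():
            status_rows.append({"block": bname, "family": fam, "status": status})
    pd.DataFrame(status_rows, columns=["block", "family", "status"]).to_csv(
        outdir / "family_status.tsv", sep=sep, index=False
    )


def read_assignments(outdir, ploidy: int) -> AssignmentResult:
    """Reload per-block haplotype-dosage matrices written by write_results."""
    from .pipeline import BlockResult

    outdir = Path(outdir)
    blocks = {}
    for path in sorted(outdir.glob("*_hapdos.tsv")):
        bname = path.name[: -len("_hapdos.tsv")]
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
        assignments = {}
        for indiv in df.columns:
            col = df[indiv]
            if col.isna().any():
                assignments[indiv] = None
            else:
                hc = []
                for code, d in col.items():
                    hc.extend([int(code)] * int(d))
                assignments[indiv] = tuple(sorted(hc))
        blocks[bname] = BlockResult(bname, [], {}, assignments, {})
    return AssignmentResult(ploidy=ploidy, blocks=blocks)


# ---------------------------------------------------------------------------
# truth sets (simulator)


def write_truth(truth_ghap: Mapping[str, Mapping[str, tuple]], path, sep: str = "\t") -> None:
    rows = [
        (b, indiv, "/".join(str(c) for c in hc))
        for b in truth_ghap
        for indiv, hc in truth_ghap[b].items()
    ]
    pd.DataFrame(rows, columns=["block", "individual", "haplotypes"]).to_csv(
        path, sep=sep, index=False
    )


def read_truth(path, sep: str = "\t"):
    df = pd.read_csv(path, sep=sep, dtype=str)
    out: dict[str, dict[str, tuple]] = {}
    for b, indiv, haps in zip(df["block"], df["individual"], df["haplotypes"]):
        out.setdefault(b, {})[indiv] = tuple(sorted(int(x) for x in haps.split("/")))
    return out
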