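"""Compound structure normalization and cross-source gene-annotation joins.

Compound-gene association sources index compounds by structure, not by
library ID, and the same chemical appears as different salt forms and
stereoisomers.  Compounds are therefore keyed by the first 14 characters
of the standard InChIKey — the connectivity block, which hashes the
molecular skeleton only — after keeping just the main component of the
structure (the longest dot-separated SMILES fragment, which strips salts
and counterions).  Annotation tables from multiple sources keyed the same
way are inner-joined against the compound library and unioned, keeping
per-source provenance.

SMILES parsing and InChIKey generation are delegated to RDKit; this
module owns component selection, truncation, and the join logic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.inchi import MolToInchiKey

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")  # parse failures are reported via our own log

_KEY_RE = re.compile(r"^[A-Z]{14}$")


def select_main_component(smiles: str) -> str:
    """Return the dot-separated component with the longest SMILES string.

    Salt and counterion fragments are shorter than the parent structure
    in virtually all library entries, so the longest fragment is kept
    (ties broken by first occurrence).  A dot-free SMILES is returned
    unchanged.  Length is measured in raw SMILES characters.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    if "." not in smiles:
        return smiles
    return max(smiles.split("."), key=len)  # max keeps the first of equal-length


def connectivity_key(smiles: str) -> str | None:
    """First 14 characters (connectivity block) of the standard InChIKey.

    The main component is selected first, so salt forms collapse to the
    parent key; the connectivity block itself is insensitive to
    stereochemistry and protonation.  Unparseable SMILES yield ``None``
    with a logged warning — attrition is expected and counted, never
    fatal.
    """
    main = select_main_component(smiles)
    mol = Chem.MolFromSmiles(main)
    if mol is None:
        logger.warning("unparseable SMILES %r; compound dropped from mapping", smiles)
        return None
    try:
        inchikey = MolToInchiKey(mol)
    except Exception:  # rare InChI generation failures on exotic structures
        logger.warning("InChIKey generation failed for %r", smiles)
        return None
    if not inchikey:
        return None
    return inchikey[:14]


@dataclass
class CompoundRecord:
    """A library compound with its structure and connectivity key."""

    compound_id: str
    smiles: str | None = None
    connectivity_key: str | None = None

    def __post_init__(self) -> None:
        if self.connectivity_key is not None and not _KEY_RE.match(self.connectivity_key):
            raise ValueError(
                f"connectivity key must be 14 uppercase letters, got "
                f"{self.connectivity_key!r}")


def key_compounds(records: list[CompoundRecord]) -> tuple[list[CompoundRecord], int]:
    """Fill connectivity keys from SMILES where missing.

    Returns the records (keys populated in place) and the count of
    compounds whose structure could not be keyed.
    """
    n_failed = 0
    for rec in records:
        if rec.connectivity_key is not None:
            continue
        if not rec.smiles:
            n_failed += 1
            continue
        key = connectivity_key(rec.smiles)
        if key is None:
            n_failed += 1
        else:
            rec.connectivity_key = key
    if n_failed:
        logger.info("key_compounds: %d of %d compounds could not be keyed",
                    n_failed, len(records))
    return records, n_failed


def read_smiles_file(path) -> list[CompoundRecord]:
    """Read a compound_id<TAB>SMILES file (no header)."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["compound_id", "smiles"],
                        dtype=str)
    return [CompoundRecord(rec.compound_id, rec.smiles)
            for rec in frame.itertuples(index=False)]


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a (source, connectivity_key, gene) annotation table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "connectivity_key", "gene"}
    if not required <= set(frame.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return frame[sorted(required)]


@dataclass
class MappingResult:
    """Joined annotations plus attrition/union bookkeeping."""

    key_annotations: pd.DataFrame       # connectivity_key, gene, sources
    compound_annotations: pd.DataFrame  # compound_id, gene, sources
    stats: dict

    def write_tsv(self, path) -> None:
        self.compound_annotations.to_csv(path, sep="\t", index=False)


def map_compounds(records: list[CompoundRecord],
                  sources: dict[str, pd.DataFrame] | list[pd.DataFrame]) -> MappingResult:
    """Join keyed compounds to annotation sources and union the sources.

    Each source table must carry (source, connectivity_key, gene) rows.
    The join is an inner join on the connectivity key restricted to the
    library's keys; (key, gene) pairs are deduplicated across sources
    with provenance retained as a sorted ``;``-joined source list.
    Compounds sharing a connectivity key stay distinct and share the
    key's annotations.

    ``stats`` reports, per source and combined, the number of mapped
    compounds and unique genes, plus key attrition in the library.
    """
    if isinstance(sources, list):
        sources = {f"source{i}": tab for i, tab in enumerate(sources)}
    keyed = [r for r in records if r.connectivity_key is not None]
    key_to_compounds: dict[str, list[str]] = {}
    for rec in keyed:
        key_to_compounds.setdefault(rec.connectivity_key, []).append(rec.compound_id)

    frames = []
    for name, tab in sources.items():
        if tab.empty:
            continue
        tab = tab[["source", "connectivity_key", "gene"]].copy()
        frames.append(tab)
    stats: dict = {
        "n_compounds": len(records),
        "n_keyed_compounds": len(keyed),
        "n_unique_keys": len(key_to_compounds),
        "per_source": {},
    }

    if frames:
        pooled = pd.concat(frames, ignore_index=True)
        pooled = pooled[(pooled["gene"].astype(str) != "") & pooled["gene"].notna()]
        pooled = pooled[pooled["connectivity_key"].isin(key_to_compounds)]
        pooled = pooled.drop_duplicates(["source", "connectivity_key", "gene"])
    else:
        pooled = pd.DataFrame(columns=["source", "connectivity_key", "gene"])

    for name in sources:
        sub = pooled[pooled["source"].isin(
            sources[name]["source"].unique() if not sources[name].empty else [])]
        mapped_keys = set(sub["connectivity_key"])
        stats["per_source"][name] = {
            "n_mapped_compounds": sum(len(key_to_compounds[k]) for k in mapped_keys),
            "n_mapped_keys": len(mapped_keys),
            "n_unique_genes": int(sub["gene"].nunique()),
        }

    if pooled.empty:
        key_ann = pd.DataFrame(columns=["connectivity_key", "gene", "sources"])
    else:
        key_ann = (pooled.groupby(["connectivity_key", "gene"])["source"]
                   .apply(lambda s: ";".join(sorted(set(s)))).reset_index()
                   .rename(columns={"source": "sources"})
                   .sort_values(["connectivity_key", "gene"], ignore_index=True))

    comp_rows = []
    for rec in key_ann.itertuples(index=False):
        for cid in key_to_compounds[rec.connectivity_key]:
            comp_rows.append((cid, rec.gene, rec.sources))
    comp_ann = pd.DataFrame(comp_rows, columns=["compound_id", "gene", "sources"])
    comp_ann = comp_ann.sort_values(["compound_id", "gene"], ignore_index=True)

    mapped_keys = set(key_ann["connectivity_key"]) if not key_ann.empty else set()
    stats["combined"] = {
        "n_mapped_compounds": int(comp_ann["compound_id"].nunique()),
        "n_mapped_keys": len(mapped_keys),
        "n_unique_genes": int(key_ann["gene"].nunique()) if not key_ann.empty else 0,
        "n_unique_pairs": len(key_ann),
    }
    logger.info("map_compounds: %d (key, gene) pairs over %d compounds, %d genes",
                len(key_ann), stats["combined"]["n_mapped_compounds"],
                stats["combined"]["n_unique_genes"])
    return MappingResult(key_ann, comp_ann, stats)
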