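#!/usr/bin/env python
"""Optional protein-scale validation against published characterization
values.  Requires network access and user-supplied inputs; it is NOT part
of the test suite or the offline acceptance script.

What it does, per protein:
  1. fetches the UniProt entry (sequence + TRANSMEM annotations),
  2. applies the QTY code and reports TM / overall variation, MW and pI
     for native and analog,
  3. if a cryo-EM PDB id and a predicted analog model file are configured,
     superposes them (both cycles=0 and cycles=5 refinement are reported,
     since published RMSDs rarely state their outlier handling),
  4. for the oxidoreductase entry, measures the FAD-heme separation under
     both distance conventions and the residues within 4 Å of the bridging
     phenylalanine.

Published reference points these numbers can be compared against:
TM variation range 37.50-54.69%, overall variation range 10.03-27.63%,
cryo-EM vs analog RMSD range 0.273-0.875 Å, FAD-heme separation 9.3 Å
with both cofactors within 4 Å of residue F359 (STEAP4 numbering).

Usage:
    python scripts/validate_paper.py --write-example-config config.json
    # edit config.json: add paths to downloaded analog models, chain ids
    python scripts/validate_paper.py --config config.json --workdir scratch/
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
from pathlib import Path

import qtykit as q

# Example configuration.  Accessions/PDB ids are editable inputs, not
# baked into the library: supply your own accession -> entry mapping.
EXAMPLE_CONFIG = {
    "proteins": {
        "MGST2": {"uniprot": "Q99735", "pdb": "6SSS", "chain": "A",
                  "analog_model": None},
        "LTC4S": {"uniprot": "Q16873", "pdb": "3PCV", "chain": "A",
                  "analog_model": None},
        "PTGES": {"uniprot": "O14684", "pdb": "4AL0", "chain": "A",
                  "analog_model": None},
        "FACE1": {"uniprot": "O75844", "pdb": "5SYT", "chain": "A",
                  "analog_model": None},
        "STEA4": {"uniprot": "Q687X5", "pdb": "6HCY", "chain": "A",
                  "analog_model": None, "cofactor_site": True},
        "SCD": {"uniprot": "O00767", "pdb": "4ZYO", "chain": "A",
                "analog_model": None},
    },
    "pairing": "align",
    "cutoff": 2.0,
}


def fetch(url: str, dest: Path) -> Path:
    if not dest.exists():
        print(f"fetching {url}", file=sys.stderr)
        urllib.request.urlretrieve(url, dest)
    return dest


def uniprot_record(acc: str, workdir: Path) -> q.ProteinRecord:
    raw = fetch(
        f"https://rest.uniprot.org/uniprotkb/{acc}.json",
        workdir / f"{acc}.json",
    ).read_text()
    entry = json.loads(raw)
    seq = entry["sequence"]["value"]
    segments = [
        q.TMSegment(f["location"]["start"]["value"],
                    f["location"]["end"]["value"])
        for f in entry.get("features", [])
        if f["type"] == "Transmembrane"
    ]
    return q.attach_segments(q.ProteinRecord(id=acc, sequence=seq), segments)


def characterize(name: str, rec: q.ProteinRecord) -> dict:
    res = q.apply_qty(rec)
    return {
        "tm_variation_pct": round(res.stats.tm_variation_pct, 2),
        "overall_variation_pct": round(res.stats.overall_variation_pct, 2),
        "mw_native": round(q.molecular_weight(rec.sequence), 2),
        "mw_analog": round(q.molecular_weight(res.analog.sequence), 2),
        "pi_native": round(q.isoelectric_point(rec.sequence), 2),
        "pi_analog": round(q.isoelectric_point(res.analog.sequence), 2),
    }


def superpose_entry(cfg: dict, pairing_policy: str, cutoff: float,
                    workdir: Path) -> dict | None:
    if not cfg.get("analog_model"):
        return None
    native = q.read_structure(
        fetch(f"https://files.rcsb.org/download/{cfg['pdb']}.pdb",
              workdir / f"{cfg['pdb']}.pdb")
    )
    native = q.extract_protomer(native, cfg["chain"])
    analog = q.read_structure(Path(cfg["analog_model"]))
    if cfg["chain"] in analog.chains and len(analog.chains) > 1:
        analog = q.extract_protomer(analog, cfg["chain"])
    pairing = q.pair_residues(native, analog, pairing_policy)
    raw = q.superpose_models(native, analog, pairing, cycles=0)
    refined = q.superpose_models(native, analog, pairing, cycles=5,
                                 cutoff=cutoff)
    return {
        "n_pairs": raw.n_pairs_used,
        "rmsd_cycles0": round(raw.rmsd, 3),
        "rmsd_cycles5": round(refined.rmsd, 3),
        "n_rejected": refined.n_rejected,
    }


def cofactor_site(pdb: str, workdir: Path) -> dict:
    model = q.read_structure(
        fetch(f"https://files.rcsb.org/download/{pdb}.pdb",
              workdir / f"{pdb}.pdb")
    )
    d_min, pair = q.min_distance(model, "resn FAD", "resn HEM")
    d_cen, _ = q.min_distance(model, "resn FAD", "resn HEM",
                              convention="centroid")
    fad = q.contact_residues(model, "resn FAD", cutoff=4.0)
    hem = q.contact_residues(model, "resn HEM", cutoff=4.0)
    bridging_phe = sorted(
        c.residue
        for c in fad.contacts
        if c.name == "PHE" and c.residue in hem.residue_keys
    )
    return {
        "fad_heme_min_heavy_atom_A": round(d_min, 2),
        "fad_heme_min_atom_pair": pair,
        "fad_heme_centroid_A": round(d_cen, 2),
        "phe_within_4A_of_both": [f"{c}{n}" for c, n, _ in bridging_phe],
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path)
    ap.add_argument("--workdir", type=Path, default=Path("scratch/validate"))
    ap.add_argument("--write-example-config", type=Path)
    ap.add_argument("--out", type=Path)
    args = ap.parse_args()

    if args.write_example_config:
        args.write_example_config.write_text(
            json.dumps(EXAMPLE_CONFIG, indent=2) + "\n"
        )
        print(f"wrote {args.write_example_config}; edit and re-run with --config")
        return
    if not args.config:
        ap.error("--config is required (see --write-example-config)")

    cfg = json.loads(args.config.read_text())
    args.workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"proteins": {}}
    tm_pcts, overall_pcts, rmsds = [], [], []
    for name, pcfg in cfg["proteins"].items():
        rec = uniprot_record(pcfg["uniprot"], args.workdir)
        entry = characterize(name, rec)
        sup = superpose_entry(pcfg, cfg.get("pairing", "align"),
                              cfg.get("cutoff", 2.0), args.workdir)
        if sup:
            entry["superposition"] = sup
            rmsds.append(sup["rmsd_cycles5"])
        if pcfg.get("cofactor_site"):
            entry["cofactor_site"] = cofactor_site(pcfg["pdb"], args.workdir)
        tm_pcts.append(entry["tm_variation_pct"])
        overall_pcts.append(entry["overall_variation_pct"])
        report["proteins"][name] = entry
    report["summary"] = {
        "tm_variation_range_pct": [min(tm_pcts), max(tm_pcts)],
        "overall_variation_range_pct": [min(overall_pcts), max(overall_pcts)],
        "rmsd_range_A": [min(rmsds), max(rmsds)] if rmsds else None,
    }
    text = json.dumps(report, indent=2) + "\n"
    if args.out:
        args.out.write_text(text)
    print(text)


if __name__ == "__main__":
    main()
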