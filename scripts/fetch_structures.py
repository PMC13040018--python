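#!/usr/bin/env python
"""Fetch the deposited coordinate files used by the accession-dependent
tests into data/structures/ (network required; run once).

Downloads the Fab/peptide complex (9Z2H), the 806/peptide comparison
complex (3G5V), the tethered EGFR ectodomain (1NQL) and the ligand-bound
dimeric ectodomain (1MOX) from the RCSB file server, then writes a
chain-role template (roles.yaml) from each file's entity annotations.
Review roles.yaml before running the tests: chain roles (peptide / heavy /
light / receptor) are configuration, never guessed by the analysis code.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["9z2h", "3g5v", "1nql", "1mox"]
DEST = Path(__file__).resolve().parents[1] / "data" / "structures"


def fetch(accession: str) -> Path:
    out = DEST / f"{accession}.cif"
    if out.exists():
        print(f"{out} already present")
        return out
    url = f"https://files.rcsb.org/download/{accession.upper()}.cif"
    print(f"fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as resp:
        out.write_bytes(resp.read())
    return out


def entity_summary(path: Path) -> list[str]:
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    lines = []
    for ent in st.entities:
        if ent.entity_type.name != "Polymer":
            continue
        lines.append(f"  # chains {list(ent.subchains)}: "
                     f"{ent.name or '?'}")
    for chain in st[0]:
        lines.append(f"  # chain {chain.name}: {len(chain)} residues")
    return lines


ROLES_TEMPLATE = """\
# Chain-role map for the deposited structures.  Fill in the chain ids after
# inspecting the files (entity summaries below); the tests refuse to guess.
#
# 9z2h holds two Fab/peptide complexes in the asymmetric unit:
#   peptide/heavy/light  = first complex, peptide2/... = second complex.
9z2h:
  peptide: FILL_ME
  heavy: FILL_ME
  light: FILL_ME
  peptide2: FILL_ME
  heavy2: FILL_ME
  light2: FILL_ME
3g5v:
  peptide: FILL_ME
  heavy: FILL_ME
  light: FILL_ME
1nql:
  receptor: FILL_ME
1mox:
  receptor: FILL_ME   # one receptor subunit of the 2:2 complex
"""


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    summaries = []
    for acc in ACCESSIONS:
        try:
            path = fetch(acc)
        except Exception as exc:  # noqa: BLE001
            print(f"ERROR fetching {acc}: {exc}", file=sys.stderr)
            return 1
        summaries.append(f"# {acc}:")
        summaries.extend(entity_summary(path))
    roles = DEST / "roles.yaml"
    if not roles.exists():
        roles.write_text(ROLES_TEMPLATE + "\n" + "\n".join(summaries) + "\n")
        print(f"wrote template {roles}; review and fill in the chain ids")
    else:
        print(f"{roles} already present, leaving it untouched")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
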