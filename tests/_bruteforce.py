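"""Independent literal-enumeration oracle for the conservation screen.

Deliberately naive: dict lookups on the published integer table read from the
tests' own fixture TSV, explicit double loops, no numpy — kept independent of
the package's vectorized implementation.
"""

from pathlib import Path

FIXTURE = Path(__file__).parent / "data" / "grantham1974_published.tsv"


def load_published_matrix() -> dict:
    """Published Grantham table as a {(a, b): int} dict (both orders)."""
    lines = FIXTURE.read_text().splitlines()
    header = lines[0].split("\t")[1:]
    mat = {}
    for line in lines[1:]:
        fields = line.split("\t")
        a = fields[0]
        for b, v in zip(header, fields[1:]):
            mat[(a, b)] = int(v)
    return mat


def brute_force_site(aligned_seqs: dict, column: int, ids: list) -> tuple:
    """Mean pairwise distance and pair count at a 1-based column, literal enumeration.

    Gaps '-' and 'X' are skipped.  Returns (mean or None, n_pairs, n_usable).
    """
    mat = load_published_matrix()
    residues = []
    for rid in ids:
        ch = aligned_seqs[rid][column - 1]
        if ch not in ("-", "X"):
            residues.append(ch)
    dists = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            dists.append(mat[(residues[i], residues[j])])
    if not dists:
        return None, 0, len(residues)
    return sum(dists) / len(dists), len(dists), len(residues)
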