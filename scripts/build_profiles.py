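"""One-off generator for the bundled consensus numbering profiles.

Run from the repo root:  python scratch/build_profiles.py

Writes plain-text profiles into src/tcrcurate/data/profiles/.  The V-domain
profiles follow the IMGT scaffold: FR1 = 1-26 with the first conserved
cysteine at 23, CDR1 slot 27-38, FR2 = 39-55 with the conserved tryptophan
at 41, CDR2 slot 56-65, FR3 = 66-104 ending at the second conserved cysteine
(104), CDR3 slot 105-117, FR4 = 118-128.  Consensus CDR lengths are 6/6/11.

MHC groove (G) domains are numbered 1..N per domain; the second groove
domain of MH1-like chains is offset by +1000 so that one chain never carries
duplicate residue identifiers.  The B2M (beta-2 microglobulin) profile places
its two conserved cysteines at the immunoglobulin C-domain positions 23 and
104.
"""

from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "tcrcurate" / "data" / "profiles"
OUT.mkdir(parents=True, exist_ok=True)


def pad(seq: str, n: int, end: str = "") -> str:
    """Deterministically pad/trim `seq` (before suffix `end`) to length n."""
    body = n - len(end)
    s = (seq + "SGSGSGSGSGSG")[:body]
    assert len(s) == body
    return s + end


def cdr_slots(lo: int, hi: int, length: int) -> list[int]:
    """IMGT middle-out occupancy of a CDR slot for a loop of given length."""
    size = hi - lo + 1
    assert length <= size
    n_left = (length + 1) // 2
    n_right = length - n_left
    return list(range(lo, lo + n_left)) + list(range(hi - n_right + 1, hi + 1))


def v_profile(fr1, cdr1, fr2, cdr2, fr3, cdr3, fr4):
    fr1 = pad(fr1, 26)
    assert fr1[22] == "C", fr1
    fr2 = pad(fr2, 17)
    assert fr2[2] == "W", fr2
    fr3 = pad(fr3, 39, end="C")
    fr4 = pad(fr4, 11)
    assert fr4[0] == "F"
    seq = fr1 + cdr1 + fr2 + cdr2 + fr3 + cdr3 + fr4
    pos = (
        list(range(1, 27))
        + cdr_slots(27, 38, len(cdr1))
        + list(range(39, 56))
        + cdr_slots(56, 65, len(cdr2))
        + list(range(66, 105))
        + cdr_slots(105, 117, len(cdr3))
        + list(range(118, 129))
    )
    assert len(seq) == len(pos)
    return seq, pos


def write_profile(name, chain_type, species, kind, seq, pos):
    lines = [
        "# tcrcurate consensus numbering profile (implementer-constructed)",
        f"name: {name}",
        f"chain_type: {chain_type}",
        f"species: {species}",
        f"kind: {kind}",
        "positions: " + " ".join(str(p) for p in pos),
        "sequence: " + seq,
    ]
    (OUT / f"{name}.txt").write_text("\n".join(lines) + "\n")
    print(f"{name}: {len(seq)} columns")


# ---------------------------------------------------------------------- TCR V
TRBV_H = dict(
    fr1="GAGVSQSPRYKVTKRGQDVALRCDPI",
    cdr1="SGHTAS",
    fr2="FYWYRQTLGQGPEFLTY",
    cdr2="FQNEAQ",
    fr3="LEKSRLLSDRFSAERPKGSQFSTLEIQRTEQGDSAMYL",
    cdr3="ASSLSGGAELY",
    fr4="FGSGTRLTVLE",
)
TRAV_H = dict(
    fr1="AQSVTQLDSHVSVSEGTPVLLRCNYS",
    cdr1="TISGNE",
    fr2="LYWYRQDPGKGLQLLLK",
    cdr2="IYSNGD",
    fr3="KEDGRFTAQLNKASQYVSLLIRDSQPSDSATYL",
    cdr3="AVRDSNYQLIW",
    fr4="FGKGTKLSVIP",
)
TRGV_H = dict(
    fr1="AGHLEQPQISSTKTLSKTARLECVVS",
    cdr1="GITISN",
    fr2="HLWWYQQKPNHGLQLLLK",  # padded/trimmed to 17 by pad()
    cdr2="YYSETE",
    fr3="RNKGNFPGRFSGRQFSNSRSEMNVSTLELGDSALYL",
    cdr3="ACDTLGMGGEY",
    fr4="FGKGTRVTVEP",
)
TRDV_H = dict(
    fr1="AQKVTQAQSSVSMPVRKAVTLNCLYE",
    cdr1="TSWWSY",
    fr2="IFWYKQLPSKEMIFLIR",
    cdr2="QGSDEQ",
    fr3="NAKSGRYSVNFKKAAKSVALTISALQLEDSAKYF",
    cdr3="ALGELSGGGSY",
    fr4="FGKGTRLHILP",
)


def mutate(d, subs):
    """A few substitutions away from the human consensus (mouse profiles)."""
    out = dict(d)
    for part, idx, aa in subs:
        s = out[part]
        out[part] = s[:idx] + aa + s[idx + 1:]
    return out


TRBV_M = mutate(TRBV_H, [("fr1", 4, "T"), ("fr2", 8, "A"), ("fr3", 6, "K"), ("fr4", 6, "K")])
TRAV_M = mutate(TRAV_H, [("fr1", 2, "G"), ("fr2", 10, "V"), ("fr3", 4, "Q"), ("fr4", 2, "R")])
TRGV_M = mutate(TRGV_H, [("fr1", 3, "P"), ("fr3", 8, "T")])
TRDV_M = mutate(TRDV_H, [("fr1", 5, "S"), ("fr3", 3, "N")])

for name, ct, sp, d in [
    ("trbv_human", "TCRB", "human", TRBV_H),
    ("trav_human", "TCRA", "human", TRAV_H),
    ("trgv_human", "TCRG", "human", TRGV_H),
    ("trdv_human", "TCRD", "human", TRDV_H),
    ("trbv_mouse", "TCRB", "mouse", TRBV_M),
    ("trav_mouse", "TCRA", "mouse", TRAV_M),
    ("trgv_mouse", "TCRG", "mouse", TRGV_M),
    ("trdv_mouse", "TCRD", "mouse", TRDV_M),
]:
    seq, pos = v_profile(**d)
    write_profile(name, ct, sp, "v_domain", seq, pos)

# ---------------------------------------------------------------------- MHC
# MH1-like groove: two G domains (G-ALPHA1 1-90, G-ALPHA2 offset +1000).
GA1 = pad("GSHSMRYFFTSVSRPGRGEPRFIAVGYVDDTQFVRFDSDAASQRMEPRAPWIEQEGPEYWDRNTRNVKAQSQTDRVDLGTLRGYYNQSEAG", 90)
GA2 = pad("SHTVQRMYGCDVGSDWRFLRGYHQYAYDGKDYIALKEDLRSWTAADMAAQTTKHKWEAAHVAEQLRAYLEGTCVEWLRRYLENGKETLQRT", 90)
MH1_POS = list(range(1, 91)) + list(range(1001, 1091))
write_profile("mh1_human", "MH1", "human", "g_domain", GA1 + GA2, MH1_POS)


def perturb(seq, step, alphabet="ASTGNQ"):
    out = list(seq)
    for i in range(0, len(out), step):
        out[i] = alphabet[(i // step) % len(alphabet)]
    return "".join(out)


write_profile("mh1_mouse", "MH1", "mouse", "g_domain", perturb(GA1 + GA2, 23), MH1_POS)
write_profile("cd1_human", "CD1", "human", "g_domain", perturb(GA1 + GA2, 11), MH1_POS)
write_profile("mr1_human", "MR1", "human", "g_domain", perturb(GA1 + GA2, 13), MH1_POS)

# MH2 groove domains: one G domain per chain.
MH2A = pad("IKEEHVIIQAEFYLNPDQSGEFMFDFDGDEIFHVDMAKKETVWRLEEFGRFASFEAQGALANIAVDKANLEIMTKRSNYTPITN", 84)
MH2B = pad("GDTRPRFLWQLKFECHFFNGTERVRLLERCIYNQEESVRFDSDVGEYRAVTELGRPDAEYWNSQKDLLEQRRAAVDTYCRHNYGVGESFT", 90)
write_profile("mh2a_human", "MH2A", "human", "g_domain", MH2A, list(range(1, 85)))
write_profile("mh2b_human", "MH2B", "human", "g_domain", MH2B, list(range(1, 91)))
write_profile("mh2a_mouse", "MH2A", "mouse", "g_domain", perturb(MH2A, 19), list(range(1, 85)))
write_profile("mh2b_mouse", "MH2B", "mouse", "g_domain", perturb(MH2B, 19), list(range(1, 91)))

# ------------------------------------------------------------------- B2M
B2M = (
    "IQRTPKIQVYSRHPAENGKSNFLNCYVSGFHPSDIEVDLLKNGERIENVEHSDLSFSKDWSFYLLYYTEFTP"
    "TEKDEYACRVNHVTLSQPKIVKWDRDM"
)
c1 = B2M.index("C")
c2 = B2M.index("C", c1 + 1)
# domain starts so that the first cysteine lands exactly on 23
start = c1 - 22
b2m_seq = B2M[start:]
c1 -= start
c2 -= start
pos = list(range(1, 24))                      # ... first Cys = 23
pos += list(range(24, 24 + (c2 - c1 - 1)))    # inter-cysteine stretch
pos += [104]                                  # second Cys = 104
pos += list(range(105, 105 + len(b2m_seq) - c2 - 1))
assert len(pos) == len(b2m_seq)
assert b2m_seq[pos.index(23)] == "C" and b2m_seq[pos.index(104)] == "C"
write_profile("b2m_human", "B2M", "human", "c_domain", b2m_seq, pos)
write_profile("b2m_mouse", "B2M", "mouse", "c_domain", perturb(b2m_seq, 17), pos)
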