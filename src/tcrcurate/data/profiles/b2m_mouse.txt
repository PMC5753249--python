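# tcrcurate consensus numbering profile (implementer-constructed)
name: b2m_mouse
chain_type: B2M
species: mouse
kind: c_domain
positions: 1 2 3 4 5 6 7 8 9 10 11 12 13 14 15 16 17 18 19 20 21 22 23 24 25 26 27 28 29 30 31 32 33 34 35 36 37 38 39 40 41 42 43 44 45 46 47 48 49 50 51 52 53 54 55 56 57 58 59 60 61 62 63 64 65 66 67 68 69 70 71 72 73 74 75 76 77 104 105 106 107 108 109 110 111 112 113 114 115 116 117 118 119 120 121 122 123
sequence: ATPKIQVYSRHPAENGKSNFLNCYVSGFHPSDIETDLLKNGERIENVEHSDGSFSKDWSFYLLYYTEFNPTEKDEYACRVNHVTLQQPKIVKWDRDM
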