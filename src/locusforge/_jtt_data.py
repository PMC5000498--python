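"""Jones-Taylor-Thornton (1992) amino-acid substitution model parameters.

Lower triangle of the symmetric exchangeability matrix (rows 2..20, PAML
residue order ARNDCQEGHILKMFPSTWYV) and the accompanying equilibrium
frequencies, as published with the model.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# fmt: off
JTT_LOWER_TRIANGLE = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]
# fmt: on

JTT_FREQUENCIES = [
    0.07674792325,
    0.05169094831,
    0.04264495736,
    0.05154394846,
    0.01980298020,
    0.04075195925,
    0.06182993817,
    0.07315192685,
    0.02294397706,
    0.05376094624,
    0.09190390810,
    0.05867594132,
    0.02382597617,
    0.04012595987,
    0.05090094910,
    0.06876493124,
    0.05856494144,
    0.01426098574,
    0.03210196790,
    0.06600493400,
]
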