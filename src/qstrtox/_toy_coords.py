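"""Frozen 3D coordinates (Angstrom) of the toy fixture molecules.

Heavy-atom coordinates in SMILES atom order, generated once from a
seeded distance-geometry embedding with force-field refinement and
stored as literals.  These are synthetic fixture geometries, not
quantum-chemically optimised structures.
"""

TOY_COORDS = {
    "methyl_methylcarbamate": [
        (-2.2982, 0.1242, 0.3459),
        (-1.0897, 0.1081, -0.4305),
        (0.1435, 0.0645, 0.1438),
        (0.3734, 0.1356, 1.3411),
        (1.0764, -0.0839, -0.8283),
        (2.4161, -0.1429, -0.3381),
    ],
    "phenyl_methylcarbamate": [
        (3.6674, 1.4410, -0.4152),
        (2.7485, 0.3369, -0.3766),
        (1.3994, 0.5216, -0.2420),
        (0.8457, 1.6122, -0.2465),
        (0.7879, -0.7126, -0.0886),
        (-0.6043, -0.6671, 0.0403),
        (-1.1608, -1.0410, 1.2619),
        (-2.5480, -1.0586, 1.4017),
        (-3.3636, -0.7175, 0.3202),
        (-2.7949, -0.3625, -0.9054),
        (-1.4084, -0.3438, -1.0520),
    ],
    "carbaryl": [
        (4.5190, 0.3405, 0.6200),
        (3.4169, -0.1699, -0.1483),
        (2.1743, -0.3462, 0.3967),
        (1.9089, -0.1919, 1.5806),
        (1.2906, -0.7102, -0.6054),
        (-0.0247, -0.9065, -0.1563),
        (-0.3400, -2.1299, 0.4399),
        (-1.6456, -2.3689, 0.8524),
        (-2.6281, -1.3961, 0.6535),
        (-2.3232, -0.1702, 0.0346),
        (-3.3173, 0.8004, -0.1735),
        (-3.0163, 2.0135, -0.7939),
        (-1.7172, 2.2737, -1.2156),
        (-0.7168, 1.3212, -1.0154),
        (-0.9984, 0.0888, -0.3878),
    ],
    "propoxur": [
        (-2.4467, -2.1281, 2.4481),
        (-2.5929, -1.1962, 1.3649),
        (-1.6859, -0.1921, 1.1547),
        (-0.7789, 0.0920, 1.9261),
        (-1.9731, 0.4279, -0.0489),
        (-1.0094, 1.3733, -0.4169),
        (-1.3037, 2.7212, -0.2094),
        (-0.3773, 3.6849, -0.5975),
        (0.8187, 3.2948, -1.2025),
        (1.0966, 1.9396, -1.4233),
        (0.1840, 0.9622, -1.0261),
        (0.3355, -0.3827, -1.2260),
        (1.6621, -0.9229, -1.2114),
        (1.5513, -2.3509, -1.7427),
        (2.2268, -0.9414, 0.2075),
    ],
    "aldicarb": [
        (-1.9153, -1.8735, 0.1794),
        (-1.7715, -0.6775, 1.1236),
        (-1.8382, -1.1621, 2.5775),
        (-3.1468, 0.5380, 0.8881),
        (-2.9249, 0.9790, -0.8580),
        (-0.4580, 0.0721, 0.9484),
        (0.3677, -0.1943, -0.0113),
        (1.4768, 0.6685, 0.0823),
        (2.3362, 0.4664, -0.9706),
        (2.1877, -0.3289, -1.8898),
        (3.4207, 1.2958, -0.8408),
        (4.5497, 1.2053, -1.7256),
    ],
    "methomyl": [
        (3.0767, 1.0100, -2.2684),
        (2.0840, 0.1428, -1.6954),
        (1.0808, 0.6270, -0.8957),
        (0.8837, 1.8175, -0.6876),
        (0.3645, -0.4223, -0.3739),
        (-0.6599, 0.0525, 0.4668),
        (-1.3688, -0.9182, 0.9467),
        (-1.1404, -2.3778, 0.6536),
        (-2.7117, -0.5737, 2.0279),
        (-2.6537, 1.2318, 2.0760),
    ],
    "carbofuran": [
        (4.3937, 1.5111, -1.1563),
        (3.6168, 0.3071, -1.0532),
        (2.6865, 0.1365, -0.0628),
        (2.5377, 0.8985, 0.8835),
        (1.9726, -1.0225, -0.3127),
        (0.9137, -1.1954, 0.5707),
        (1.0545, -2.0517, 1.6625),
        (-0.0289, -2.2501, 2.5327),
        (-1.2511, -1.6053, 2.3088),
        (-1.3703, -0.7799, 1.2013),
        (-0.3048, -0.5846, 0.3411),
        (-0.5820, 0.2483, -0.7100),
        (-2.0118, 0.5073, -0.6208),
        (-2.6930, -0.2601, -1.7607),
        (-2.2198, 2.0111, -0.8078),
        (-2.5219, 0.0402, 0.7626),
    ],
    "carbamic_acid": [
        (-1.0108, -0.0061, 0.1398),
        (0.2999, 0.2562, 0.0316),
        (0.8541, 1.3129, 0.2577),
        (0.9610, -0.8308, -0.3733),
    ],
    "tert_butyl_carbamate": [
        (-1.2305, -1.1370, -0.2661),
        (-0.5299, 0.1735, 0.1099),
        (-1.2068, 0.7496, 1.3630),
        (-0.6168, 1.2117, -1.0144),
        (0.8457, -0.0592, 0.5077),
        (1.7343, -0.5705, -0.3683),
        (1.5342, -0.8876, -1.5279),
        (2.9388, -0.6940, 0.2317),
    ],
    "propham": [
        (-3.9977, -0.3427, -0.9512),
        (-2.9184, -0.5151, 0.1109),
        (-3.3348, 0.1553, 1.4153),
        (-1.7237, 0.1111, -0.3941),
        (-0.5452, -0.3404, 0.1161),
        (-0.4560, -1.2238, 0.9539),
        (0.4617, 0.3670, -0.4753),
        (1.8468, 0.2580, -0.2700),
        (2.6740, 1.1112, -1.0117),
        (4.0627, 1.0636, -0.8637),
        (4.6366, 0.1617, 0.0281),
        (3.8217, -0.6904, 0.7697),
        (2.4317, -0.6430, 0.6218),
    ],
    "ethyl_dimethylcarbamate": [
        (2.9241, -0.1264, 0.3419),
        (2.0176, 0.5011, -0.7004),
        (0.6963, 0.6739, -0.1690),
        (-0.1393, -0.3951, -0.2813),
        (0.1853, -1.4569, -0.8005),
        (-1.3935, -0.1460, 0.2529),
        (-2.4404, -1.1330, 0.0756),
        (-1.8005, 1.1656, 0.7256),
    ],
    "amino_butanol": [
        (2.4665, -0.1649, 0.4284),
        (1.5399, 0.5808, -0.4146),
        (0.1443, 0.6777, 0.2052),
        (-0.5708, -0.6740, 0.3100),
        (-1.9630, -0.5524, 0.9203),
        (-2.8259, 0.1943, 0.0744),
    ],
    "hexylamine": [
        (-2.7912, 0.6581, 1.0593),
        (-2.5554, -0.6678, 0.5010),
        (-1.4054, -0.6682, -0.5078),
        (-0.0537, -0.3114, 0.1204),
        (1.0726, -0.3882, -0.9138),
        (2.4608, -0.1447, -0.3180),
        (2.6557, 1.2675, 0.2118),
    ],
    "ethanol": [
        (-0.8883, 0.1670, -0.0273),
        (0.4658, -0.5116, -0.0368),
        (1.4311, 0.3229, 0.5867),
    ],
    "isobutane": [
        (-0.8492, -1.0752, -0.4785),
        (-0.1557, -0.0191, 0.3793),
        (1.3441, -0.2944, 0.4614),
        (-0.4154, 1.3793, -0.1765),
    ],
    "neopentane": [
        (0.7270, -1.3399, 0.1830),
        (-0.0000, 0.0000, 0.0000),
        (-1.4051, -0.2531, -0.5648),
        (0.7920, 0.8830, -0.9748),
        (-0.1139, 0.7099, 1.3566),
    ],
    "methylbutane": [
        (1.7319, 0.5896, 0.1967),
        (0.6566, 0.4876, -0.8764),
        (-0.6754, -0.1346, -0.4199),
        (-0.5134, -1.5851, 0.0352),
        (-1.3607, 0.6927, 0.6677),
    ],
    "dimethylbutane": [
        (1.4680, -0.3255, 0.8958),
        (0.7484, 0.4090, -0.2387),
        (1.2595, -0.1061, -1.5886),
        (-0.8004, 0.3476, -0.1513),
        (-1.3273, 1.0917, 1.0806),
        (-1.3718, -1.0728, -0.1752),
    ],
    "trimethylpentane": [
        (-1.4984, 1.6475, 0.8595),
        (-1.3826, 0.1681, 0.4785),
        (-2.0104, -0.0896, -0.8924),
        (0.0627, -0.4066, 0.6369),
        (-0.0481, -1.9203, 0.9202),
        (1.0587, -0.1428, -0.5396),
        (1.2678, 1.3435, -0.8425),
        (2.4398, -0.7648, -0.2706),
    ],
    "benzene": [
        (0.8077, -1.1370, 0.0184),
        (1.3887, 0.1309, -0.0046),
        (0.5809, 1.2679, -0.0231),
        (-0.8077, 1.1370, -0.0184),
        (-1.3887, -0.1309, 0.0046),
        (-0.5809, -1.2679, 0.0231),
    ],
    "toluene": [
        (2.2117, -0.1717, 0.1137),
        (0.7201, -0.0518, 0.0125),
        (0.0942, 1.1877, 0.1943),
        (-1.2964, 1.2935, 0.1314),
        (-2.0729, 0.1604, -0.1033),
        (-1.4600, -1.0799, -0.2709),
        (-0.0695, -1.1870, -0.2082),
    ],
    "pyridine": [
        (-0.0963, 1.1799, 0.0098),
        (-1.2356, 0.3819, 0.0102),
        (-1.0721, -0.9942, -0.0015),
        (0.1313, -1.6079, -0.0133),
        (1.2192, -0.8070, -0.0134),
        (1.1573, 0.5774, -0.0023),
    ],
    "pentane": [
        (-2.1729, -0.3996, 0.3594),
        (-1.2600, 0.3541, -0.5953),
        (0.0911, 0.7276, 0.0182),
        (0.9606, -0.4851, 0.3525),
        (2.3308, -0.0619, 0.8600),
    ],
    "butyne": [
        (-2.0595, 0.0398, 0.1247),
        (-0.5993, 0.0116, 0.0363),
        (0.5993, -0.0116, -0.0363),
        (2.0595, -0.0398, -0.1247),
    ],
    "cyclooctane": [
        (1.6669, 0.0577, 0.2532),
        (1.3767, -1.3890, -0.1425),
        (-0.0505, -1.7299, -0.5737),
        (-1.1568, -1.3022, 0.3879),
        (-1.7812, 0.0663, 0.0872),
        (-1.0889, 1.2506, 0.7580),
        (-0.0212, 1.9592, -0.0767),
        (1.0763, 1.0963, -0.6969),
    ],
    "triethylamine": [
        (1.9458, -0.8458, -0.4126),
        (0.8531, -0.3559, 0.5278),
        (-0.2961, 0.1267, -0.2579),
        (-0.5566, 1.5590, -0.0329),
        (0.5407, 2.4517, -0.6056),
        (-1.5150, -0.6567, 0.0079),
        (-1.4215, -2.0848, -0.5221),
    ],
}
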