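{
"version": 1,
"width": 323,
"blocks": {
"const": 30,
"conn": 23,
"prop": 6,
"kappa": 7,
"charge": 12,
"maccs": 166,
"estate": 79
},
"labels": [
"const.n_heavy",
"const.n_atoms_total",
"const.n_hydrogens",
"const.n_C",
"const.n_N",
"const.n_O",
"const.n_S",
"const.n_P",
"const.n_F",
"const.n_Cl",
"const.n_Br",
"const.n_I",
"const.n_heteroatoms",
"const.n_halogens",
"const.n_bonds",
"const.n_single_bonds",
"const.n_double_bonds",
"const.n_triple_bonds",
"const.n_aromatic_bonds",
"const.n_rotatable_bonds",
"const.n_rings",
"const.n_aromatic_rings",
"const.mol_weight",
"const.n_hbd",
"const.n_hba",
"const.path_count_1",
"const.path_count_2",
"const.path_count_3",
"const.path_count_4",
"const.path_count_5",
"conn.chi0p",
"conn.chi1p",
"conn.chi2p",
"conn.chi3p",
"conn.chi4p",
"conn.chi5p",
"conn.chi6p",
"conn.chi3c",
"conn.chi4c",
"conn.mean_chi1",
"conn.chi0pv",
"conn.chi1pv",
"conn.chi2pv",
"conn.chi3pv",
"conn.chi4pv",
"conn.chi5pv",
"conn.chi6pv",
"conn.chi3cv",
"conn.chi4cv",
"conn.mean_chi1v",
"conn.chi0n",
"conn.chi1n",
"conn.chi2n",
"prop.logp",
"prop.molar_refractivity",
"prop.tpsa",
"prop.labute_asa",
"prop.fraction_csp3",
"prop.bertz_ct",
"kappa.kappa1",
"kappa.kappa2",
"kappa.kappa3",
"kappa.kappa1_alpha",
"kappa.kappa2_alpha",
"kappa.kappa3_alpha",
"kappa.hall_kier_alpha",
"charge.q_max",
"charge.q_min",
"charge.q_pos_total",
"charge.q_neg_total",
"charge.q_abs_total",
"charge.q_mean",
"charge.q_abs_mean",
"charge.q_variance",
"charge.q_max_relative",
"charge.q_min_relative",
"charge.q_net_balance",
"charge.q_squared_total",
"maccs.key1",
"maccs.key2",
"maccs.key3",
"maccs.key4",
"maccs.key5",
"maccs.key6",
"maccs.key7",
"maccs.key8",
"maccs.key9",
"maccs.key10",
"maccs.key11",
"maccs.key12",
"maccs.key13",
"maccs.key14",
"maccs.key15",
"maccs.key16",
"maccs.key17",
"maccs.key18",
"maccs.key19",
"maccs.key20",
"maccs.key21",
"maccs.key22",
"maccs.key23",
"maccs.key24",
"maccs.key25",
"maccs.key26",
"maccs.key27",
"maccs.key28",
"maccs.key29",
"maccs.key30",
"maccs.key31",
"maccs.key32",
"maccs.key33",
"maccs.key34",
"maccs.key35",
"maccs.key36",
"maccs.key37",
"maccs.key38",
"maccs.key39",
"maccs.key40",
"maccs.key41",
"maccs.key42",
"maccs.key43",
"maccs.key44",
"maccs.key45",
"maccs.key46",
"maccs.key47",
"maccs.key48",
"maccs.key49",
"maccs.key50",
"maccs.key51",
"maccs.key52",
"maccs.key53",
"maccs.key54",
"maccs.key55",
"maccs.key56",
"maccs.key57",
"maccs.key58",
"maccs.key59",
"maccs.key60",
"maccs.key61",
"maccs.key62",
"maccs.key63",
"maccs.key64",
"maccs.key65",
"maccs.key66",
"maccs.key67",
"maccs.key68",
"maccs.key69",
"maccs.key70",
"maccs.key71",
"maccs.key72",
"maccs.key73",
"maccs.key74",
"maccs.key75",
"maccs.key76",
"maccs.key77",
"maccs.key78",
"maccs.key79",
"maccs.key80",
"maccs.key81",
"maccs.key82",
"maccs.key83",
"maccs.key84",
"maccs.key85",
"maccs.key86",
"maccs.key87",
"maccs.key88",
"maccs.key89",
"maccs.key90",
"maccs.key91",
"maccs.key92",
"maccs.key93",
"maccs.key94",
"maccs.key95",
"maccs.key96",
"maccs.key97",
"maccs.key98",
"maccs.key99",
"maccs.key100",
"maccs.key101",
"maccs.key102",
"maccs.key103",
"maccs.key104",
"maccs.key105",
"maccs.key106",
"maccs.key107",
"maccs.key108",
"maccs.key109",
"maccs.key110",
"maccs.key111",
"maccs.key112",
"maccs.key113",
"maccs.key114",
"maccs.key115",
"maccs.key116",
"maccs.key117",
"maccs.key118",
"maccs.key119",
"maccs.key120",
"maccs.key121",
"maccs.key122",
"maccs.key123",
"maccs.key124",
"maccs.key125",
"maccs.key126",
"maccs.key127",
"maccs.key128",
"maccs.key129",
"maccs.key130",
"maccs.key131",
"maccs.key132",
"maccs.key133",
"maccs.key134",
"maccs.key135",
"maccs.key136",
"maccs.key137",
"maccs.key138",
"maccs.key139",
"maccs.key140",
"maccs.key141",
"maccs.key142",
"maccs.key143",
"maccs.key144",
"maccs.key145",
"maccs.key146",
"maccs.key147",
"maccs.key148",
"maccs.key149",
"maccs.key150",
"maccs.key151",
"maccs.key152",
"maccs.key153",
"maccs.key154",
"maccs.key155",
"maccs.key156",
"maccs.key157",
"maccs.key158",
"maccs.key159",
"maccs.key160",
"maccs.key161",
"maccs.key162",
"maccs.key163",
"maccs.key164",
"maccs.key165",
"maccs.key166",
"estate.type1",
"estate.type2",
"estate.type3",
"estate.type4",
"estate.type5",
"estate.type6",
"estate.type7",
"estate.type8",
"estate.type9",
"estate.type10",
"estate.type11",
"estate.type12",
"estate.type13",
"estate.type14",
"estate.type15",
"estate.type16",
"estate.type17",
"estate.type18",
"estate.type19",
"estate.type20",
"estate.type21",
"estate.type22",
"estate.type23",
"estate.type24",
"estate.type25",
"estate.type26",
"estate.type27",
"estate.type28",
"estate.type29",
"estate.type30",
"estate.type31",
"estate.type32",
"estate.type33",
"estate.type34",
"estate.type35",
"estate.type36",
"estate.type37",
"estate.type38",
"estate.type39",
"estate.type40",
"estate.type41",
"estate.type42",
"estate.type43",
"estate.type44",
"estate.type45",
"estate.type46",
"estate.type47",
"estate.type48",
"estate.type49",
"estate.type50",
"estate.type51",
"estate.type52",
"estate.type53",
"estate.type54",
"estate.type55",
"estate.type56",
"estate.type57",
"estate.type58",
"estate.type59",
"estate.type60",
"estate.type61",
"estate.type62",
"estate.type63",
"estate.type64",
"estate.type65",
"estate.type66",
"estate.type67",
"estate.type68",
"estate.type69",
"estate.type70",
"estate.type71",
"estate.type72",
"estate.type73",
"estate.type74",
"estate.type75",
"estate.type76",
"estate.type77",
"estate.type78",
"estate.type79"
]
}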