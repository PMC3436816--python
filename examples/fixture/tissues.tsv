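G0000	tissue1
G0001	tissue1
G0002	tissue2
G0003	tissue1
G0004	tissue2
G0005	tissue2
G0006	tissue3
G0007	tissue2
G0008	tissue3
G0009	tissue2
G0010	tissue2
G0011	tissue1
G0012	tissue3
G0013	tissue2
G0014	tissue1
G0015	tissue1
G0016	tissue1
G0016	tissue_planted
G0017	tissue3
G0018	tissue2
G0019	tissue2
G0020	tissue2
G0021	tissue3
G0022	tissue2
G0023	tissue3
G0024	tissue3
G0025	tissue1
G0026	tissue1
G0027	tissue2
G0028	tissue2
G0029	tissue3
G0030	tissue3
G0031	tissue2
G0031	tissue_planted
G0032	tissue1
G0032	tissue_planted
G0033	tissue1
G0034	tissue2
G0035	tissue3
G0036	tissue2
G0037	tissue3
G0038	tissue3
G0039	tissue3
G0039	tissue_planted
G0040	tissue3
G0041	tissue2
G0042	tissue3
G0043	tissue3
G0044	tissue2
G0045	tissue2
G0046	tissue2
G0047	tissue2
G0048	tissue1
G0048	tissue_planted
G0049	tissue3
G0050	tissue2
G0051	tissue1
G0052	tissue1
G0053	tissue3
G0054	tissue3
G0055	tissue1
G0056	tissue2
G0056	tissue_planted
G0057	tissue2
G0058	tissue3
G0059	tissue3
G0060	tissue1
G0061	tissue1
G0062	tissue3
G0063	tissue2
G0063	tissue_planted
G0064	tissue1
G0065	tissue2
G0066	tissue3
G0067	tissue1
G0068	tissue3
G0069	tissue3
G0070	tissue3
G0071	tissue1
G0072	tissue3
G0073	tissue2
G0074	tissue1
G0074	tissue_planted
G0075	tissue2
G0075	tissue_planted
G0076	tissue3
G0077	tissue1
G0078	tissue2
G0079	tissue1
G0080	tissue1
G0081	tissue3
G0082	tissue1
G0083	tissue1
G0084	tissue2
G0085	tissue2
G0086	tissue1
G0087	tissue3
G0088	tissue3
G0088	tissue_planted
G0089	tissue3
G0090	tissue2
G0091	tissue2
G0092	tissue3
G0093	tissue1
G0094	tissue3
G0095	tissue1
G0096	tissue3
G0097	tissue3
G0098	tissue1
G0098	tissue_planted
G0099	tissue2
G0100	tissue2
G0101	tissue3
G0102	tissue3
G0103	tissue2
G0104	tissue1
G0105	tissue3
G0106	tissue3
G0107	tissue2
G0108	tissue2
G0109	tissue1
G0110	tissue3
G0111	tissue2
G0111	tissue_planted
G0112	tissue3
G0113	tissue3
G0114	tissue3
G0115	tissue1
G0116	tissue3
G0117	tissue1
G0118	tissue3
G0119	tissue2
G0120	tissue2
G0120	tissue_planted
G0121	tissue2
G0122	tissue2
G0123	tissue3
G0124	tissue1
G0125	tissue2
G0126	tissue1
G0127	tissue2
G0128	tissue3
G0129	tissue3
G0130	tissue2
G0131	tissue2
G0132	tissue3
G0133	tissue3
G0134	tissue3
G0135	tissue1
G0136	tissue2
G0137	tissue3
G0138	tissue2
G0139	tissue1
G0140	tissue3
G0140	tissue_planted
G0141	tissue2
G0142	tissue2
G0143	tissue1
G0144	tissue2
G0145	tissue1
G0146	tissue3
G0147	tissue3
G0148	tissue3
G0149	tissue3
G0150	tissue1
G0150	tissue_planted
G0151	tissue1
G0152	tissue3
G0153	tissue3
G0154	tissue2
G0154	tissue_planted
G0155	tissue2
G0156	tissue2
G0156	tissue_planted
G0157	tissue3
G0157	tissue_planted
G0158	tissue2
G0159	tissue3
G0160	tissue2
G0161	tissue2
G0162	tissue2
G0162	tissue_planted
G0163	tissue1
G0164	tissue2
G0165	tissue2
G0166	tissue2
G0167	tissue2
G0167	tissue_planted
G0168	tissue2
G0169	tissue2
G0170	tissue3
G0171	tissue1
G0172	tissue3
G0172	tissue_planted
G0173	tissue1
G0174	tissue1
G0175	tissue1
G0176	tissue3
G0177	tissue3
G0178	tissue3
G0179	tissue1
G0180	tissue1
G0181	tissue3
G0182	tissue2
G0183	tissue1
G0184	tissue2
G0185	tissue3
G0186	tissue1
G0187	tissue1
G0188	tissue3
G0189	tissue1
G0190	tissue1
G0191	tissue3
G0192	tissue3
G0193	tissue1
G0194	tissue2
G0195	tissue1
G0196	tissue3
G0197	tissue2
G0198	tissue3
G0198	tissue_planted
G0199	tissue1
G0200	tissue2
G0201	tissue2
G0202	tissue1
G0203	tissue1
G0204	tissue3
G0205	tissue2
G0206	tissue3
G0207	tissue2
G0208	tissue3
G0208	tissue_planted
G0209	tissue1
G0210	tissue3
G0211	tissue1
G0212	tissue1
G0212	tissue_planted
G0213	tissue2
G0214	tissue2
G0215	tissue1
G0216	tissue3
G0217	tissue3
G0218	tissue1
G0219	tissue2
G0219	tissue_planted
G0220	tissue1
G0221	tissue1
G0222	tissue2
G0223	tissue3
G0224	tissue3
G0225	tissue1
G0226	tissue2
G0227	tissue2
G0228	tissue1
G0229	tissue1
G0230	tissue3
G0231	tissue2
G0232	tissue1
G0233	tissue1
G0234	tissue2
G0235	tissue1
G0236	tissue2
G0237	tissue3
G0238	tissue2
G0239	tissue2
G0240	tissue2
G0241	tissue1
G0242	tissue1
G0243	tissue3
G0244	tissue1
G0245	tissue1
G0246	tissue2
G0247	tissue2
G0248	tissue2
G0249	tissue1
G0250	tissue2
G0251	tissue2
G0252	tissue3
G0253	tissue2
G0253	tissue_planted
G0254	tissue3
G0254	tissue_planted
G0255	tissue3
G0256	tissue1
G0257	tissue3
G0258	tissue1
G0259	tissue2
G0260	tissue2
G0260	tissue_planted
G0261	tissue1
G0262	tissue3
G0263	tissue1
G0264	tissue2
G0265	tissue1
G0266	tissue1
G0267	tissue1
G0268	tissue1
G0269	tissue1
G0270	tissue2
G0271	tissue2
G0272	tissue1
G0273	tissue1
G0274	tissue3
G0275	tissue2
G0276	tissue1
G0277	tissue1
G0278	tissue3
G0279	tissue3
G0280	tissue3
G0280	tissue_planted
G0281	tissue3
G0282	tissue2
G0283	tissue1
G0284	tissue1
G0285	tissue3
G0286	tissue3
G0287	tissue2
G0287	tissue_planted
G0288	tissue3
G0289	tissue3
G0290	tissue3
G0291	tissue1
G0292	tissue1
G0293	tissue1
G0294	tissue2
G0295	tissue3
G0296	tissue3
G0297	tissue1
G0298	tissue3
G0299	tissue2
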