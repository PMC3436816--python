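PW1	synthetic pathway PW1	G0016	G0031	G0032	G0039	G0048	G0056	G0063	G0074	G0075	G0088	G0098	G0111	G0120	G0140	G0150	G0154	G0156	G0157	G0162	G0167	G0172	G0198	G0208	G0212	G0219	G0253	G0254	G0260	G0280	G0287
PW2	synthetic pathway PW2	G0006	G0012	G0020	G0037	G0044	G0045	G0069	G0087	G0091	G0103	G0106	G0109	G0129	G0138	G0145	G0159	G0161	G0176	G0178	G0182	G0187	G0193	G0194	G0197	G0200	G0207	G0218	G0241	G0245	G0278
PW3	synthetic pathway PW3	G0001	G0010	G0011	G0024	G0046	G0054	G0060	G0065	G0066	G0076	G0079	G0086	G0090	G0092	G0097	G0116	G0134	G0166	G0205	G0209	G0213	G0216	G0221	G0240	G0249	G0274	G0277	G0281	G0284	G0294
PW4	synthetic pathway PW4	G0013	G0017	G0029	G0033	G0040	G0071	G0094	G0107	G0110	G0125	G0126	G0128	G0163	G0174	G0175	G0179	G0181	G0188	G0190	G0191	G0204	G0210	G0214	G0228	G0235	G0238	G0282	G0292	G0293	G0299
PW5	synthetic pathway PW5	G0002	G0007	G0009	G0023	G0027	G0038	G0078	G0082	G0095	G0101	G0105	G0112	G0115	G0118	G0141	G0143	G0160	G0169	G0171	G0183	G0202	G0229	G0230	G0246	G0248	G0271	G0275	G0285	G0289	G0296
PW6	synthetic pathway PW6	G0004	G0021	G0030	G0034	G0051	G0057	G0077	G0083	G0096	G0114	G0123	G0127	G0136	G0144	G0158	G0168	G0177	G0201	G0206	G0233	G0234	G0247	G0251	G0255	G0256	G0259	G0265	G0268	G0276	G0297
PW7	synthetic pathway PW7	G0018	G0041	G0049	G0050	G0053	G0055	G0059	G0070	G0132	G0135	G0139	G0147	G0148	G0151	G0170	G0189	G0192	G0215	G0222	G0224	G0226	G0236	G0239	G0242	G0252	G0257	G0263	G0267	G0283	G0291
PW8	synthetic pathway PW8	G0005	G0014	G0022	G0026	G0052	G0058	G0061	G0072	G0073	G0081	G0085	G0099	G0117	G0119	G0121	G0122	G0131	G0133	G0152	G0153	G0164	G0173	G0195	G0203	G0211	G0232	G0244	G0273	G0279	G0298
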