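sample_id	group	treatment_score	pH	SMC	NH4	NO3	IN	DOC	DON	TC	TN	comm_axis1	comm_axis2	biomass	yield
CK_1	CK	-1.224744871391589	6.413323963501659	11.84670730525461	2.580747502130067	9.001469803308156	14.947700261303059	15.053580948159329	0.22260529266101403	41.39044809295079	2.4662098172363676	-1.3812947159236413	-1.4190465079583383	42.6465305080745	2.505668287539624
CK_2	CK	-1.224744871391589	6.380085253579286	12.875743042331225	2.9882354986560835	12.35635254089159	15.529475961719436	16.195931710165027	0.2279290704380009	41.665597235975326	2.412873374815294	-0.792783058444165	-0.2338385013777335	37.46669363992807	2.1249192186180252
CK_3	CK	-1.224744871391589	6.363846260771191	11.754439388118456	2.7356199803934858	11.501240731889466	12.828795512585321	14.558169605787718	0.19934569365505833	40.339391177872436	2.4164259395667025	-1.9435153917372836	-1.9207760515232608	39.566358839611084	2.079541585022871
CK_4	CK	-1.224744871391589	6.399044861198881	12.007199952491906	2.8000125605760244	11.987245749236761	13.098968713534301	16.182506256482156	0.21025752083340243	42.70272787398832	2.5485149082886096	-1.3957765289261588	-1.3814202700439675	48.780052967889134	2.705556718531752
CK_5	CK	-1.224744871391589	6.45808166484538	12.81901100040351	3.104049728986863	11.496854623268993	15.117123205127701	15.463220603379519	0.25159498291018456	43.272903852123065	2.5185639428620368	-0.0569921100891556	0.0315116280378301	51.511048197882516	3.3204207903251057
CK_6	CK	-1.224744871391589	6.268994152070084	10.882178906567248	2.432293667307673	6.704691547144046	10.814023766669692	12.133703482214191	0.11245092855174513	38.884384921176746	2.2424749625219227	-2.1259346391264873	-2.5508046787413945	43.120350395445755	2.2329817738461544
M_1	M	0.0	6.598676479085393	13.130355722454045	3.1453701449353737	14.089681728384909	15.982697775201107	16.674674430079154	0.29451934589982653	43.16431250861572	2.535958263644313	0.5148969363571165	1.5397136982478552	58.163694141711225	3.166522206118946
M_2	M	0.0	6.529697117159659	12.655619267451925	2.977163380657331	12.014457594477209	16.999573992933513	16.55340866418	0.25413224701016174	43.320238282302206	2.6005643651768713	0.07128414814419383	0.016852143044400768	51.27983118527255	2.6986372820417253
M_3	M	0.0	6.627508324409674	12.79226891698079	3.1968096563750463	13.018465427246326	16.39104908893623	16.938262816540835	0.30613091516370805	42.928603654717165	2.6051638183183212	-0.1698438784205213	-0.31008446354682473	51.959644635026386	2.680076824584189
M_4	M	0.0	6.696922087325932	13.177119094757169	3.316476878610579	15.399893995243618	18.98945096730133	18.028613872608762	0.32148170370207685	44.07812536858683	2.785728161510062	0.6657248634854843	0.20553477862959973	67.47481691247293	3.839350703239291
M_5	M	0.0	6.572096611927683	13.230626946068371	3.0532486458401884	14.200169043283328	17.91009511150305	17.543974187357087	0.27020205393350605	42.51192237205565	2.600796825984799	-0.06695076364437863	0.23739343773858088	58.45446579823479	2.952094391764787
M_6	M	0.0	6.451569691864769	12.245349351949574	2.845002734231141	14.291997673255057	13.979183287757477	16.407200238203615	0.2319579155850483	42.166851646491025	2.499531735883542	1.2158480946250134	1.0989633026194194	50.454878100595074	2.8467668845402025
bioM_1	bioM	1.224744871391589	6.865498844254621	14.6225361277662	3.8771806353370044	19.284326919485807	22.354312204269718	21.122353762632038	0.448500745200729	46.583248971193186	2.9858134611609732	1.640933454159919	1.3815989451281374	54.011497198545946	3.067696387935518
bioM_2	bioM	1.224744871391589	6.697625887366867	13.38676826089458	3.3622587217363606	16.78390028617333	18.885977072253105	19.248537237148497	0.36852418497789896	45.24350885326096	2.8184953754871063	1.084092575352126	1.6094893848195568	63.80661575218499	3.555960450724374
bioM_3	bioM	1.224744871391589	6.579667585043043	12.553411325094403	3.044055938637666	13.173379616140409	17.65508872290323	16.7374037240244	0.27838771733266116	42.1134781748245	2.5664380509906954	1.019580270540281	1.2842492186450407	55.61191468740377	2.9737597457376914
bioM_4	bioM	1.224744871391589	6.581503164530125	12.9507741474161	3.179746954608976	14.959115395009087	19.5270708682923	17.279682300816383	0.3079962350199452	43.50286703079894	2.7021599473034565	0.26111876578408977	0.7277521435701515	44.22366431022789	2.693451149915251
bioM_5	bioM	1.224744871391589	6.668547998452564	13.747824886135616	3.5142682942364494	16.860910488733246	21.47069726653465	19.090133103618687	0.3481945047637908	44.78890542453836	2.8124345872756025	0.4659034015559124	1.221106360604418	51.339688422015	2.6521681819364664
bioM_6	bioM	1.224744871391589	6.3681795926727345	12.096278297245012	2.624970619164694	10.788605767464912	12.580197488306526	13.551763707421834	0.18646507477690447	39.89003569473675	2.3022645775174655	0.623838808805899	0.392819506614615	49.05900264775611	3.0367971444468935
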