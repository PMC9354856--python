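substance_id	abbreviation	label
Allyl alcohol	AA	toxic
2-acetamidofluorene	AAF	toxic
α-naphthyl isothiocyanate	ANIT	toxic
Acetaminophen	APAP	toxic
Aspirin	ASA	toxic
Benzbromarone	BBr	toxic
Bromobenzene	BBZ	toxic
Bucetin	BCT	toxic
Bendazac	BDZ	toxic
Benziodarone	BZD	toxic
Carboplatin	CBP	toxic
Coumarin	CMA	toxic
Chlormezanone	CMN	toxic
Chloramphenicol	CMP	toxic
Colchicine	COL	toxic
Cyclophosphamide monohydrate	CPA	toxic
Clomipramine hydrochloride	CPM	toxic
Chlorpropamide	CPP	toxic
Cyclosporine A	CPA	toxic
Diltiazem hydrochloride	DIL	toxic
Disopyramide	DIS	toxic
Disulfiram	DSF	toxic
Dantrolene sodium hemiheptahydrate	DTL	toxic
Diazepam	DZP	toxic
Ethambutol dihydrochloride	EBU	toxic
17-α-Ethinylestradiol	EE	toxic
DL-Ethionine	ET	toxic
Fenofibrate	FFB	toxic
Flutamide	FT	toxic
Gemfibrozil	GFZ	toxic
Hexachlorobenzene	HCB	toxic
Lomustine	LS	toxic
Mexiletine hydrochloride	MEX	toxic
Methapyrilene hydrochloride	MP	toxic
Methyltestosterone	MTS	toxic
Methimazole	MTZ	toxic
Nimesulide	NIM	toxic
Phenacetin	PCT	toxic
Promethazine hydrochloride	PMZ	toxic
Propylthiouracil	PTU	toxic
Sulfasalazine	SS	toxic
Simvastatin	SST	toxic
Sulindac	SUL	toxic
Thioacetamide	TAA	toxic
Terbinafine hydrochloride	TBF	toxic
Ticlopidine hydrochloride	TCP	toxic
Trimethadione	TMD	toxic
Vitamin A	VA	toxic
WY-14643	WY	toxic
Acarbose	ACA	non_toxic
Acetazolamide	ACZ	non_toxic
Adapin	ADP	non_toxic
Ajmaline	AJM	non_toxic
Amiodarone hydrochloride	AM	non_toxic
Amitriptyline hydrochloride	AMT	non_toxic
Allopurinol	APL	non_toxic
2-Bromoethylamine hydrobromide	BEA	non_toxic
Caffeine	CAF	non_toxic
Captopril	CAP	non_toxic
Carbamazepine	CBZ	non_toxic
Clofibrate	CFB	non_toxic
Chlorpheniramine maleate	CHL	non_toxic
Cimetidine	CIM	non_toxic
Chlormadinone acetate	CLM	non_toxic
Cephalothin sodium	CLT	non_toxic
Ciprofloxacin hydrochloride	CPX	non_toxic
Chlorpromazine hydrochloride	CPZ	non_toxic
Diclofenac sodium	DFNa	non_toxic
Danazol	DNZ	non_toxic
Erythromycin ethylsuccinate	EME	non_toxic
Enalapril maleate	ENA	non_toxic
Ethanol	ETN	non_toxic
Etoposide	ETP	non_toxic
Famotidine	FAM	non_toxic
Fluphenazine dihydrochloride	FP	non_toxic
Furosemide	FUR	non_toxic
Glibenclamide	GBC	non_toxic
Griseofulvin	GF	non_toxic
Gentamicin sulfate	GMC	non_toxic
Haloperidol	HPL	non_toxic
Hydroxyzine dihydrochloride	HYZ	non_toxic
Ibuprofen	IBU	non_toxic
Imipramine hydrochloride	IMI	non_toxic
Isoniazid	INAH	non_toxic
Iproniazid phosphate	IPA	non_toxic
Ketoconazole	KC	non_toxic
Methyldopa	MDP	non_toxic
Mefenamic acid	MEF	non_toxic
Metformin hydrochloride	MFM	non_toxic
Moxisylyte hydrochloride	MXS	non_toxic
Nitrofurantoin	NFT	non_toxic
Nitrofurazone	NFZ	non_toxic
Nicotinic acid	NIC	non_toxic
Nifedipine	NIF	non_toxic
Omeprazole	OPZ	non_toxic
Papaverine hydrochloride	PAP	non_toxic
Phenobarbital sodium	PB	non_toxic
D-penicillamine	PEN	non_toxic
Perhexiline maleate	PH	non_toxic
Phenylbutazone	PhB	non_toxic
Phenytoin	PHE	non_toxic
Pemoline	PML	non_toxic
Quinidine sulfate	QND	non_toxic
Ranitidine hydrochloride	RAN	non_toxic
Rifampicin	RIF	non_toxic
Sulpiride	SLP	non_toxic
Tannic acid	TAN	non_toxic
Tetracycline hydrochloride	TC	non_toxic
Tiopronin	TIO	non_toxic
Tolbutamide	TLB	non_toxic
Tamoxifen citrate	TMX	non_toxic
Triamterene	TRI	non_toxic
Thioridazine hydrochloride	TRZ	non_toxic
Triazolam	TZM	non_toxic
Sodium valproate	VPA	non_toxic
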