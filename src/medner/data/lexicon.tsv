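# Default drug/term lexicon: phrase<TAB>field_code
# Medication names (generic and brand), plus a small set of reason terms.
percocet	m
lasix	m
tylenol	m
aspirin	m
acetaminophen	m
ibuprofen	m
naproxen	m
metformin	m
lisinopril	m
atenolol	m
metoprolol	m
carvedilol	m
amlodipine	m
nifedipine	m
diltiazem	m
verapamil	m
losartan	m
valsartan	m
irbesartan	m
hydrochlorothiazide	m
furosemide	m
spironolactone	m
bumetanide	m
torsemide	m
chlorthalidone	m
simvastatin	m
atorvastatin	m
pravastatin	m
rosuvastatin	m
lovastatin	m
ezetimibe	m
gemfibrozil	m
fenofibrate	m
niacin	m
warfarin	m
coumadin	m
heparin	m
enoxaparin	m
lovenox	m
clopidogrel	m
plavix	m
ticlopidine	m
dipyridamole	m
digoxin	m
amiodarone	m
sotalol	m
flecainide	m
quinidine	m
procainamide	m
insulin	m
glipizide	m
glyburide	m
glimepiride	m
pioglitazone	m
rosiglitazone	m
sitagliptin	m
acarbose	m
levothyroxine	m
synthroid	m
methimazole	m
propylthiouracil	m
prednisone	m
prednisolone	m
methylprednisolone	m
dexamethasone	m
hydrocortisone	m
fludrocortisone	m
omeprazole	m
prilosec	m
pantoprazole	m
protonix	m
lansoprazole	m
esomeprazole	m
ranitidine	m
famotidine	m
cimetidine	m
sucralfate	m
misoprostol	m
ondansetron	m
zofran	m
metoclopramide	m
reglan	m
promethazine	m
prochlorperazine	m
docusate	m
colace	m
senna	m
bisacodyl	m
lactulose	m
polyethylene	m
miralax	m
loperamide	m
amoxicillin	m
ampicillin	m
penicillin	m
augmentin	m
cephalexin	m
cefazolin	m
ceftriaxone	m
cefepime	m
azithromycin	m
clarithromycin	m
erythromycin	m
ciprofloxacin	m
levofloxacin	m
moxifloxacin	m
doxycycline	m
tetracycline	m
minocycline	m
clindamycin	m
metronidazole	m
flagyl	m
vancomycin	m
linezolid	m
gentamicin	m
tobramycin	m
nitrofurantoin	m
trimethoprim	m
bactrim	m
fluconazole	m
nystatin	m
acyclovir	m
valacyclovir	m
oseltamivir	m
morphine	m
oxycodone	m
hydrocodone	m
vicodin	m
codeine	m
tramadol	m
fentanyl	m
hydromorphone	m
dilaudid	m
methadone	m
gabapentin	m
neurontin	m
pregabalin	m
lyrica	m
carbamazepine	m
phenytoin	m
dilantin	m
valproate	m
depakote	m
levetiracetam	m
keppra	m
lamotrigine	m
topiramate	m
sertraline	m
zoloft	m
fluoxetine	m
prozac	m
paroxetine	m
citalopram	m
celexa	m
escitalopram	m
lexapro	m
venlafaxine	m
duloxetine	m
bupropion	m
mirtazapine	m
trazodone	m
amitriptyline	m
nortriptyline	m
lithium	m
quetiapine	m
seroquel	m
risperidone	m
olanzapine	m
zyprexa	m
haloperidol	m
haldol	m
aripiprazole	m
lorazepam	m
ativan	m
diazepam	m
valium	m
alprazolam	m
xanax	m
clonazepam	m
klonopin	m
midazolam	m
temazepam	m
zolpidem	m
ambien	m
buspirone	m
albuterol	m
ventolin	m
ipratropium	m
atrovent	m
fluticasone	m
flovent	m
budesonide	m
montelukast	m
singulair	m
theophylline	m
tamsulosin	m
flomax	m
finasteride	m
oxybutynin	m
tolterodine	m
allopurinol	m
colchicine	m
probenecid	m
cyclobenzaprine	m
baclofen	m
tizanidine	m
methotrexate	m
hydroxychloroquine	m
sulfasalazine	m
azathioprine	m
cyclosporine	m
tacrolimus	m
mycophenolate	m
epoetin	m
filgrastim	m
ferrous sulfate	m
calcium carbonate	m
vitamin d	m
vitamin b12	m
folic acid	m
magnesium oxide	m
potassium chloride	m
caltrate plus d	m
fish oil	m
nitroglycerin	m
isosorbide dinitrate	m
isosorbide mononitrate	m
fluocinonide 0.5% cream	m
# Reason terms (symptoms / indications)
fever	r
pain	r
chest pain	r
back pain	r
dizziness	r
nausea	r
vomiting	r
constipation	r
diarrhea	r
insomnia	r
anxiety	r
agitation	r
depression	r
hypertension	r
diabetes	r
hyperlipidemia	r
infection	r
pneumonia	r
cough	r
wheezing	r
edema	r
headache	r
reflux	r
seizures	r
rare angina	r
frequent pvcs	r
atrial fibrillation	r
heart failure	r
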