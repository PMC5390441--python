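acronym,study_name,study_type,n_variables,n_participants,use
AIR,Atherosclerosis and Insulin Resistance study,general population,136,435,Construction
ARIC,Atherosclerosis risk in communities,general population,10108,15042,Validation
BCAPS,Beta-blocker Cholesterol-lowering Asymptomatic Plaque Study,RCT,134,1544,Validation
BHS,Bogalusa Heart Study,general population,1220,1986,Construction
BKRE,Konyang University Hospital CIMT Registry,RCT,109,205,Validation
Bruneck,Bruneck Study,general population,141,821,Validation
CAPS,Carotid Atherosclerosis Progression Study,general population,692,6972,Construction
CCCC,Chin-Shan Community Cardiovascular Cohort Study,general population,110,3603,Construction
CHS,Cardiovascular Health Study,general population,1426,5901,Construction
CIMT_TIME,CIMT TIME Project,risk population,144,671,Validation
CMCS-Beijing,Chinese Multi-provincial Cohort Study-Beijing,general population,141,1324,Construction
CREED,Cardiovascular Risk Extended Evaluation in Dialysis patients,risk population,53,138,Construction
DIWA,"Diabetes, Impaired glucose tolerance in Women and Atherosclerosis",general population,129,644,Validation
EAS,Edinburgh Artery Study,general population,74,1593,Construction
Ekart et al.,None,risk population,102,54,Construction
EPICARDIAN,Cardiovascular Epidemiology in the Elderly in Spain,general population,76,446,Construction
EVA,Etude du Vieillissement Arteriel,general population,212,1135,Validation
HD-IMT,Carotid ultrasonographic parameters in patients on hemodialysis,risk population,130,85,Validation
HOORN,The Hoorn Study,general population,128,3103,Construction
IMPROVE,IMT and IMT-Progression as Predictors of Vascular Events,risk population,103,3703,Construction
INVADE,Interventionsprojekt zerebrovaskulaere Erkrankungen und Demenz,general population,1581,3365,Validation
Kato et al.,None,risk population,131,284,Validation
KIHD,Kuopio Ischemic Heart Disease Risk Factor Study,general population,151,1399,Construction
Landecho et al.,None,risk population,69,248,Validation
Niguarda,Niguarda-Monzino Study,risk population,88,1564,Construction
NOMAS/INVEST,Northern Manhattan Study,general population,334,857,Validation
OSACA,Osaca Follow-Up Study for Carotid Atherosclerosis,risk population,108,291,Construction
Papagianni et al.,None,risk population,73,84,Construction
PIVUS,Prospective Investigation of the Vasculature in Uppsala Seniors,general population,98,1017,Validation
PLIC,Progression of Lesions in the Intima of the Carotid,general population,264,2607,Validation
RIAS,Resistive Index in AtheroSclerosis,risk population,67,158,Construction
Rotterdam,Rotterdam Study,general population,34,7983,Validation
SAPHIR,Salzburg Atherosclerosis Prevention program,general population,141,3127,Validation
SHIP,Study of Health in Pomerania,general population,320,4308,Construction
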