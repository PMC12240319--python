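# SYNTHETIC stand-in for the MedDRA SMQ "Drug related hepatic disorders -
# severe events only" (code 20000007, narrow scope, 144 PTs).
# The authoritative PT list is distributed under a MedDRA license and is NOT
# reproduced here; this file contains 144 plausible hepatic-disorder
# Preferred Term strings so that the pipeline and its tests are runnable
# out of the box. Users holding a MedDRA license should replace this file
# with the licensed narrow-scope term list (one PT per line, "#" comments).
Acute graft versus host disease in liver
Acute hepatic failure
Acute on chronic liver failure
Acute yellow liver atrophy
Allergic hepatitis
Ammonia abnormal
Ammonia increased
Ascites
Asterixis
Autoimmune hepatitis
Bacterial hepatitis
Bile output abnormal
Biliary cirrhosis
Bilirubin conjugated abnormal
Bilirubin conjugated increased
Bilirubin urine present
Blood bilirubin abnormal
Blood bilirubin increased
Blood bilirubin unconjugated increased
Cholaemia
Cholestasis
Cholestatic liver injury
Cholestatic pruritus
Chronic hepatic failure
Chronic hepatitis
Coma hepatic
Cryptogenic cirrhosis
Cytolytic hepatitis
Diabetic hepatopathy
Drug-induced liver injury
Duodenal varices
Foetor hepaticus
Gallbladder varices
Gastric varices
Gastric varices haemorrhage
Graft versus host disease in liver
Granulomatous liver disease
Haemorrhagic hepatic cyst
Hepaplastin abnormal
Hepaplastin decreased
Hepatectomy
Hepatic atrophy
Hepatic calcification
Hepatic cirrhosis
Hepatic cytolysis
Hepatic encephalopathy
Hepatic encephalopathy prophylaxis
Hepatic failure
Hepatic fibrosis
Hepatic function abnormal
Hepatic hydrothorax
Hepatic hypertrophy
Hepatic infiltration eosinophilic
Hepatic lesion
Hepatic mass
Hepatic necrosis
Hepatic pain
Hepatic sequestration
Hepatic steato-fibrosis
Hepatic steatosis
Hepatic vascular resistance increased
Hepatitis
Hepatitis acute
Hepatitis cholestatic
Hepatitis chronic active
Hepatitis chronic persistent
Hepatitis fulminant
Hepatitis neonatal
Hepatitis toxic
Hepatobiliary disease
Hepatocellular foamy cell syndrome
Hepatocellular injury
Hepatomegaly
Hepatopulmonary syndrome
Hepatorenal failure
Hepatorenal syndrome
Hepatosplenomegaly
Hepatotoxicity
Hepatic enzyme abnormal
Hepatic enzyme decreased
Hepatic enzyme increased
Hypertransaminasaemia
Hyperammonaemia
Hyperbilirubinaemia
Icterus index increased
Immune-mediated hepatic disorder
Immune-mediated hepatitis
Ischaemic hepatitis
Jaundice
Jaundice cholestatic
Jaundice hepatocellular
Liver and small intestine transplant
Liver disorder
Liver function test abnormal
Liver function test decreased
Liver function test increased
Liver induration
Liver injury
Liver opacity
Liver palpable
Liver sarcoidosis
Liver scan abnormal
Liver tenderness
Liver transplant
Lupoid hepatic cirrhosis
Lupus hepatitis
Mixed liver injury
Model for end stage liver disease score abnormal
Model for end stage liver disease score increased
Molecular adsorbent recirculating system therapy
Nodular regenerative hyperplasia
Non-alcoholic fatty liver disease
Non-alcoholic steatohepatitis
Non-cirrhotic portal hypertension
Ocular icterus
Oedema due to hepatic disease
Oesophageal varices
Oesophageal varices haemorrhage
Periportal oedema
Perihepatic discomfort
Portal fibrosis
Portal hypertension
Portal hypertensive enteropathy
Portal hypertensive gastropathy
Portal shunt procedure
Portal vein dilatation
Portopulmonary hypertension
Radiation hepatitis
Renal and liver transplant
Retrograde portal vein flow
Reye's syndrome
Reynold's syndrome
Small-for-size liver syndrome
Splenic varices
Steatohepatitis
Subacute hepatic failure
Subacute hepatitis
Total bile acids increased
Toxic liver disease
Transaminases abnormal
Transaminases increased
Varices oesophageal
Varicose veins of abdominal wall
White nipple sign
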